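"""Generate familiarization and test stimuli for one grammar condition.

Builds the /di/-final grammar (strings AABCD/di/), draws the 36
grammatical familiarization sequences and a 36-item presence-violation
test set, shows a few transcriptions, and renders one item as MBROLA
.pho text.
"""

from collections import Counter

from aglearn import stimuli

grammar = stimuli.GrammarSpec("di_last")

fam = stimuli.generate_familiarization(grammar, n=36, seed=1)
print(f"familiarization: {len(fam)} items, e.g.")
for item in fam.items[:3]:
    print("  ", item.transcription)
# Each line is a six-syllable string: an immediately repeated syllable,
# three further syllables, then the constant affix /di/.

test = stimuli.generate_test_set(grammar, "presence", seed=2)
print(f"\ntest set: {len(test)} items:", dict(Counter(i.item_type for i in test)))
for item_type in stimuli.ITEM_TYPES:
    example = next(i for i in test if i.item_type == item_type)
    print(f"  {item_type:18s} {example.transcription}")
# Grammatical items keep both regularities; the violation types drop the
# repetition, the affix, or both. Test syllables never occur in
# familiarization (the inventories are disjoint).

print("\n.pho rendering of the first test item (12 phones x 116 ms = 1392 ms):")
print(stimuli.render_pho(test.items[0]))
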