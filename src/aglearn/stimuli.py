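"""Artificial-grammar stimulus generation.

Two mirror-image grammars generate six-syllable strings. Under the
``di_first`` grammar every string starts with the constant syllable /di/ and
ends with an immediate syllable repetition (/di/ABCDD); under ``di_last`` the
repetition opens the string and /di/ closes it (AABCD/di/). A, B, C and D are
CV-syllable categories built from fixed consonant and vowel sets; the
familiarization and test phases use disjoint syllable inventories so that
test items are always made of novel syllables.

Ungrammatical test items either lack a regularity entirely ("presence"
violations) or carry it displaced away from its grammatical edge ("position"
violations). Each test set holds 9 items of each of four types: grammatical,
repetition violation, /di/ violation, and double violation.

Phone labels are X-SAMPA-style ASCII; a diphthong is a single phone, so every
six-syllable item is exactly 12 phones.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

# --------------------------------------------------------------------------
# Phones, syllables, inventories
# --------------------------------------------------------------------------

CONSONANTS_SONORANT = ("m", "n", "l", "r", "p", "g")
CONSONANTS_OBSTRUENT = ("f", "v", "s", "z", "b", "k")
VOWELS_FRONT = ("eI", "aI", "OI", "oU")   # ei, ai, oi, ou diphthongs
VOWELS_BACK = ("A", "U", "o", "aU")       # open/back vowels

ALL_CONSONANTS = frozenset(CONSONANTS_SONORANT + CONSONANTS_OBSTRUENT + ("d",))
ALL_VOWELS = frozenset(VOWELS_FRONT + VOWELS_BACK + ("i",))

ORDERS = ("di_first", "di_last")
VIOLATION_MODES = ("presence", "position")
ITEM_TYPES = ("grammatical", "rep_violation", "di_violation", "double_violation")

RESAMPLE_CAP = 10_000


@dataclass(frozen=True)
class Syllable:
    """A CV syllable: consonant onset plus vowel/diphthong nucleus."""

    onset: str
    nucleus: str

    def __post_init__(self) -> None:
        if self.onset not in ALL_CONSONANTS:
            raise ValueError(f"unknown onset consonant {self.onset!r}")
        if self.nucleus not in ALL_VOWELS:
            raise ValueError(f"unknown nucleus vowel {self.nucleus!r}")

    @property
    def label(self) -> str:
        return self.onset + self.nucleus

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


DI = Syllable("d", "i")


def _cross(consonants: Iterable[str], vowels: Iterable[str]) -> tuple[Syllable, ...]:
    return tuple(Syllable(c, v) for c in consonants for v in vowels)


@dataclass(frozen=True)
class InventoryPhase:
    """Category -> syllable pools for one experimental phase.

    Categories A and B share one 24-syllable pool and C and D another; the
    test phase swaps the consonant sets between the pools so the two phases
    are fully disjoint. /di/ is the constant affix syllable in both phases.
    """

    phase: str
    pools: dict[str, tuple[Syllable, ...]]

    def pool(self, category: str) -> tuple[Syllable, ...]:
        if category == "DI":
            return (DI,)
        try:
            return self.pools[category]
        except KeyError:
            raise KeyError(f"unknown syllable category {category!r}") from None

    @property
    def content_syllables(self) -> frozenset[Syllable]:
        return frozenset(s for pool in self.pools.values() for s in pool)


def build_inventory(phase: str) -> InventoryPhase:
    """Return the category->syllable mapping for a phase.

    Familiarization: A/B = {m,n,l,r,p,g} x {eI,aI,OI,oU},
    C/D = {f,v,s,z,b,k} x {A,U,o,aU}. For the test phase the consonant sets
    are exchanged between the category pairs, yielding 4 x 24 mutually
    disjoint content syllables across the two phases (97 distinct syllables
    including /di/).
    """
    if phase == "familiarization":
        ab = _cross(CONSONANTS_SONORANT, VOWELS_FRONT)
        cd = _cross(CONSONANTS_OBSTRUENT, VOWELS_BACK)
    elif phase == "test":
        ab = _cross(CONSONANTS_OBSTRUENT, VOWELS_FRONT)
        cd = _cross(CONSONANTS_SONORANT, VOWELS_BACK)
    else:
        raise ValueError(f"unknown phase {phase!r}; expected 'familiarization' or 'test'")
    return InventoryPhase(phase=phase, pools={"A": ab, "B": ab, "C": cd, "D": cd})


def syllable_universe_size() -> int:
    """Number of distinct syllables across both phases plus /di/."""
    syls = build_inventory("familiarization").content_syllables
    syls |= build_inventory("test").content_syllables
    return len(syls | {DI})


# --------------------------------------------------------------------------
# Grammars and templates
# --------------------------------------------------------------------------

# Slot tokens: A/B/C/D draw from the named category pool, DI is /di/, E/F are
# foil slots whose category rotates across the 9 items of a type. A repeated
# token denotes an exact self-repeat of the same syllable.
_TEMPLATES: dict[tuple[str, str, str], tuple[str, ...]] = {
    # presence violations: a regularity is absent from the string
    ("di_first", "presence", "grammatical"): ("DI", "A", "B", "C", "D", "D"),
    ("di_first", "presence", "rep_violation"): ("DI", "A", "B", "C", "D", "E"),
    ("di_first", "presence", "di_violation"): ("E", "A", "B", "C", "D", "D"),
    ("di_first", "presence", "double_violation"): ("A", "B", "C", "D", "E", "F"),
    ("di_last", "presence", "grammatical"): ("A", "A", "B", "C", "D", "DI"),
    ("di_last", "presence", "rep_violation"): ("A", "B", "C", "D", "E", "DI"),
    ("di_last", "presence", "di_violation"): ("A", "A", "B", "C", "D", "E"),
    ("di_last", "presence", "double_violation"): ("A", "B", "C", "D", "E", "F"),
    # position violations: the regularity is present but displaced off-edge
    ("di_first", "position", "grammatical"): ("DI", "A", "B", "C", "D", "D"),
    ("di_first", "position", "rep_violation"): ("DI", "A", "B", "C", "C", "D"),
    ("di_first", "position", "di_violation"): ("A", "DI", "B", "C", "D", "D"),
    ("di_first", "position", "double_violation"): ("A", "DI", "B", "C", "C", "D"),
    ("di_last", "position", "grammatical"): ("A", "A", "B", "C", "D", "DI"),
    ("di_last", "position", "rep_violation"): ("A", "B", "B", "C", "D", "DI"),
    ("di_last", "position", "di_violation"): ("A", "A", "B", "C", "DI", "D"),
    ("di_last", "position", "double_violation"): ("A", "B", "B", "C", "DI", "D"),
}


@dataclass(frozen=True)
class GrammarSpec:
    """One of the two grammars, identified by where /di/ sits.

    ``di_first`` strings are /di/ABCDD (repetition at the end); ``di_last``
    strings are AABCD/di/ (repetition at the start).
    """

    order: str

    def __post_init__(self) -> None:
        if self.order not in ORDERS:
            raise ValueError(f"unknown grammar order {self.order!r}")

    @property
    def di_slot(self) -> int:
        """0-based slot of /di/ in grammatical strings (edge slot)."""
        return 0 if self.order == "di_first" else 5

    @property
    def repeat_pair(self) -> tuple[int, int]:
        """0-based adjacent slot pair carrying the grammatical repetition."""
        return (4, 5) if self.order == "di_first" else (0, 1)

    def template(self, item_type: str, violation_mode: str) -> tuple[str, ...]:
        key = (self.order, violation_mode, item_type)
        if key not in _TEMPLATES:
            raise KeyError(
                f"no template for item_type={item_type!r}, mode={violation_mode!r}"
            )
        return _TEMPLATES[key]


@dataclass(frozen=True)
class StimulusItem:
    """A six-syllable string with its design metadata."""

    syllables: tuple[Syllable, ...]
    order: str
    phase: str
    item_type: str
    violation_mode: str
    item_id: str

    def __post_init__(self) -> None:
        if len(self.syllables) != 6:
            raise ValueError("a stimulus item has exactly 6 syllables")

    @property
    def transcription(self) -> str:
        return "".join(s.label for s in self.syllables)


@dataclass
class StimulusSet:
    items: list[StimulusItem]
    role: str  # familiarization | test

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def classify_item(
    syllables: Sequence[Syllable], grammar: GrammarSpec
) -> tuple[str, str]:
    """Classify a six-syllable string against a grammar.

    Checks each regularity for presence anywhere and for presence at its
    grammatical edge slot, maps the pair of edge checks to one of the four
    item types, and reports the violation mode: ``presence`` if any violated
    regularity is absent from the string altogether, ``position`` if every
    violated regularity is present but displaced, ``none`` for grammatical
    items. Total on 6-tuples; never raises for well-formed input.
    """
    if len(syllables) != 6:
        raise ValueError("classify_item expects exactly 6 syllables")
    syllables = tuple(syllables)

    has_di = DI in syllables
    di_at_edge = syllables[grammar.di_slot] == DI
    repeat_pairs = [i for i in range(5) if syllables[i] == syllables[i + 1]]
    i, j = grammar.repeat_pair
    rep_at_edge = syllables[i] == syllables[j]
    has_rep = bool(repeat_pairs)

    if di_at_edge and rep_at_edge:
        return "grammatical", "none"
    if di_at_edge:
        item_type = "rep_violation"
        violated_present = [has_rep]
    elif rep_at_edge:
        item_type = "di_violation"
        violated_present = [has_di]
    else:
        item_type = "double_violation"
        violated_present = [has_rep, has_di]
    mode = "position" if all(violated_present) else "presence"
    return item_type, mode


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def _pair_distinct(a: Syllable, b: Syllable) -> bool:
    """Both consonant and vowel differ (discriminability constraint)."""
    return a.onset != b.onset and a.nucleus != b.nucleus


def _foil_category(template: tuple[str, ...], slot: int, rotation: int) -> str:
    """Category for a foil slot: rotate through A..D, skipping categories of
    template-adjacent slots (a category-D syllable never serves as the foil
    next to the D slot, which would invite an accidental repeat)."""
    adjacent = set()
    if slot > 0:
        adjacent.add(template[slot - 1])
    if slot < 5:
        adjacent.add(template[slot + 1])
    cycle = ["A", "B", "C", "D"]
    for k in range(4):
        cat = cycle[(rotation + k) % 4]
        if cat not in adjacent:
            return cat
    raise RuntimeError("no admissible foil category")  # pragma: no cover


def _sample_item(
    rng: np.random.Generator,
    grammar: GrammarSpec,
    inventory: InventoryPhase,
    item_type: str,
    violation_mode: str,
    rotation: int,
) -> tuple[Syllable, ...]:
    template = grammar.template(item_type, violation_mode)
    for _ in range(RESAMPLE_CAP):
        chosen: dict[str, Syllable] = {"DI": DI}
        foil_rot = rotation
        for slot, token in enumerate(template):
            if token in chosen:
                continue  # self-repeat reuses the same syllable
            if token in ("E", "F"):
                cat = _foil_category(template, slot, foil_rot)
                foil_rot += 1
            else:
                cat = token
            pool = inventory.pool(cat)
            chosen[token] = pool[rng.integers(len(pool))]
        seq = tuple(chosen[t] for t in template)

        # discriminability: same-zone category pairs differ in C and in V
        if "A" in chosen and "B" in chosen and not _pair_distinct(chosen["A"], chosen["B"]):
            continue
        if "C" in chosen and "D" in chosen and not _pair_distinct(chosen["C"], chosen["D"]):
            continue
        # no accidental adjacent repeats outside the template's repeat slot
        ok = True
        for k in range(5):
            if seq[k] == seq[k + 1] and template[k] != template[k + 1]:
                ok = False
                break
        if not ok:
            continue
        if classify_item(seq, grammar) != (
            item_type,
            "none" if item_type == "grammatical" else violation_mode,
        ):
            continue  # pragma: no cover - templates are classification-true
        return seq
    raise RuntimeError(
        f"could not satisfy constraints for {item_type}/{violation_mode} "
        f"within {RESAMPLE_CAP} resamples"
    )


def generate_familiarization(
    grammar: GrammarSpec, n: int = 36, seed: int = 0
) -> StimulusSet:
    """Generate ``n`` distinct grammatical familiarization items.

    Within each item the A and B syllables differ in both consonant and
    vowel, as do the two distinct final-zone syllables (C and D); the
    repeated syllable is an exact self-repeat. Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    inventory = build_inventory("familiarization")
    rng = np.random.default_rng(seed)
    items: list[StimulusItem] = []
    seen: set[tuple[Syllable, ...]] = set()
    attempts = 0
    while len(items) < n:
        attempts += 1
        if attempts > RESAMPLE_CAP * max(n, 1):
            raise RuntimeError(
                f"cannot construct {n} distinct items under the constraints"
            )
        seq = _sample_item(rng, grammar, inventory, "grammatical", "presence", len(items))
        if seq in seen:
            continue
        seen.add(seq)
        items.append(
            StimulusItem(
                syllables=seq,
                order=grammar.order,
                phase="familiarization",
                item_type="grammatical",
                violation_mode="none",
                item_id=f"fam_{grammar.order}_{len(items):03d}",
            )
        )
    return StimulusSet(items=items, role="familiarization")


def generate_test_set(
    grammar: GrammarSpec,
    violation_mode: str,
    seed: int = 0,
    n_per_type: int = 9,
) -> StimulusSet:
    """Generate a test set: ``n_per_type`` items of each of the four types.

    Foil syllables cycle through the A-D categories across the items of a
    type (counterbalancing), never land next to a slot of their own category,
    and never create an unintended adjacent repetition. Items are drawn from
    the test-phase inventory, disjoint from familiarization. Deterministic
    given ``seed``.
    """
    if violation_mode not in VIOLATION_MODES:
        raise ValueError(f"unknown violation mode {violation_mode!r}")
    inventory = build_inventory("test")
    rng = np.random.default_rng(seed)
    items: list[StimulusItem] = []
    seen: set[tuple[Syllable, ...]] = set()
    for item_type in ITEM_TYPES:
        made = 0
        attempts = 0
        while made < n_per_type:
            attempts += 1
            if attempts > RESAMPLE_CAP * max(n_per_type, 1):
                raise RuntimeError(
                    f"cannot construct {n_per_type} distinct {item_type} items"
                )
            seq = _sample_item(rng, grammar, inventory, item_type, violation_mode, made)
            if seq in seen:
                continue
            seen.add(seq)
            mode = "none" if item_type == "grammatical" else violation_mode
            items.append(
                StimulusItem(
                    syllables=seq,
                    order=grammar.order,
                    phase="test",
                    item_type=item_type,
                    violation_mode=mode,
                    item_id=f"test_{grammar.order}_{violation_mode}_{item_type}_{made:02d}",
                )
            )
            made += 1
    return StimulusSet(items=items, role="test")


# --------------------------------------------------------------------------
# MBROLA .pho rendering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthesisSpec:
    """Synthesis parameters: per-phone duration (ms) and a flat pitch (Hz)."""

    phone_duration: float = 116.0
    pitch: float = 135.0

    def __post_init__(self) -> None:
        if self.phone_duration <= 0:
            raise ValueError("phone_duration must be positive")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")


def render_pho(item: StimulusItem, spec: SynthesisSpec | None = None) -> str:
    """Render an item as MBROLA ``.pho`` text.

    One line per phone (``PHONE DURATION_MS 50 PITCH_HZ``: a single pitch
    target at the phone midpoint), 12 phone lines per item; the total
    duration is 12 x phone_duration (1392 ms at the 116 ms default).
    """
    spec = spec or SynthesisSpec()
    lines = []
    for syl in item.syllables:
        for phone in (syl.onset, syl.nucleus):
            if phone not in ALL_CONSONANTS and phone not in ALL_VOWELS:
                raise ValueError(f"phone {phone!r} not in the synthesis alphabet")
            lines.append(f"{phone} {spec.phone_duration:g} 50 {spec.pitch:g}")
    return "\n".join(lines) + "\n"


def total_duration_ms(item: StimulusItem, spec: SynthesisSpec | None = None) -> float:
    spec = spec or SynthesisSpec()
    return 2 * len(item.syllables) * spec.phone_duration


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

_CSV_COLUMNS = ["item_id", "phase", "order", "violation_mode", "item_type",
                "syl1", "syl2", "syl3", "syl4", "syl5", "syl6"]


def parse_syllable(label: str) -> Syllable:
    """Parse a space-free CV label (single-char onset + vowel label)."""
    if len(label) < 2:
        raise ValueError(f"syllable label too short: {label!r}")
    return Syllable(label[0], label[1:])


def write_stimulus_csv(stim_set: StimulusSet, path) -> None:
    """Write a stimulus set as CSV (one row per item, syllables space-free)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for item in stim_set:
            writer.writerow(
                [item.item_id, item.phase, item.order, item.violation_mode,
                 item.item_type] + [s.label for s in item.syllables]
            )


def read_stimulus_csv(path, role: str | None = None) -> StimulusSet:
    """Read a stimulus CSV back into a :class:`StimulusSet`.

    Raises ``ValueError`` naming the offending row on wrong arity or unknown
    phones. ``role`` defaults to the phase of the first item.
    """
    items: list[StimulusItem] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _CSV_COLUMNS:
            raise ValueError(f"unexpected stimulus CSV header: {header}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_CSV_COLUMNS):
                raise ValueError(
                    f"row {lineno}: expected {len(_CSV_COLUMNS)} fields, got {len(row)}"
                )
            item_id, phase, order, mode, item_type, *syls = row
            try:
                syllables = tuple(parse_syllable(s) for s in syls)
            except ValueError as exc:
                raise ValueError(f"row {lineno}: {exc}") from None
            items.append(
                StimulusItem(
                    syllables=syllables, order=order, phase=phase,
                    item_type=item_type, violation_mode=mode, item_id=item_id,
                )
            )
    if role is None:
        role = items[0].phase if items else "test"
    return StimulusSet(items=items, role=role)
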