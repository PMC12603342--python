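"""Word stimuli, trial sequences, and word-property matching.

A session presents 300 visually displayed object words drawn from a pool of
200 (100 odor-related, 100 control): 100 words are shown once and 100 twice,
in randomized order, each for 0.5 s followed by a uniformly jittered
1.7-2.3 s post-stimulus interval (continuous recognition paradigm).

The packaged word-property table is synthetic: it encodes the group means
and standard deviations of the matched psycholinguistic properties
(syllables, frequency, concreteness, arousal, imageability, valence) and of
the odor-relatedness ratings via deterministic value constructions, so the
matching t-tests are reproducible without the original German word norms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RATING_FIELDS",
    "MATCHED_PROPERTIES",
    "TRIAL_COLUMNS",
    "ValidationError",
    "WordItem",
    "WordList",
    "TTestResult",
    "load_word_list",
    "default_word_list",
    "build_matched_word_list",
    "make_trial_sequence",
    "summary_stat_ttest",
    "compare_word_properties",
]

#: rating-type properties constrained to the 1-10 rating scale
RATING_FIELDS = ("concreteness", "arousal", "imageability", "valence", "odor_rating")

#: properties the two word groups are matched on (odor_rating is the contrast)
MATCHED_PROPERTIES = (
    "syllables",
    "frequency",
    "concreteness",
    "arousal",
    "imageability",
    "valence",
)

WORD_COLUMNS = (
    "label",
    "is_odor",
    "is_living",
    "is_food",
    "syllables",
    "frequency",
    "concreteness",
    "arousal",
    "imageability",
    "valence",
    "odor_rating",
)

TRIAL_COLUMNS = (
    "trial_index",
    "onset_s",
    "word",
    "is_odor",
    "is_living",
    "is_food",
    "presentation",
)


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


@dataclass(frozen=True)
class WordItem:
    """A stimulus word with category flags and psycholinguistic properties.

    Ratings (concreteness, arousal, imageability, valence, odor_rating) live
    on a 1-10 scale; frequency is occurrences per million; syllables is a
    positive count.  Missing ratings are allowed (``None``) and are skipped
    by the matching tests.
    """

    label: str
    is_odor: bool
    is_living: bool = False
    is_food: bool = False
    syllables: int = 1
    frequency: float | None = None
    concreteness: float | None = None
    arousal: float | None = None
    imageability: float | None = None
    valence: float | None = None
    odor_rating: float | None = None

    def __post_init__(self) -> None:
        if self.syllables < 1:
            raise ValidationError(f"word {self.label!r}: syllables must be >= 1")
        if self.frequency is not None and self.frequency < 0:
            raise ValidationError(f"word {self.label!r}: frequency must be >= 0")
        for name in RATING_FIELDS:
            value = getattr(self, name)
            if value is not None and not (1.0 <= value <= 10.0):
                raise ValidationError(
                    f"word {self.label!r}: {name}={value} outside the 1-10 rating scale"
                )


@dataclass
class WordList:
    """An ordered collection of :class:`WordItem` with unique labels."""

    items: list[WordItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [w.label for w in self.items]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate word labels: {dupes}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def n_odor(self) -> int:
        return sum(w.is_odor for w in self.items)

    @property
    def n_control(self) -> int:
        return len(self.items) - self.n_odor

    def values(self, prop: str, odor: bool) -> np.ndarray:
        """Non-missing values of ``prop`` for one word group."""
        out = [
            getattr(w, prop)
            for w in self.items
            if w.is_odor == odor and getattr(w, prop) is not None
        ]
        return np.asarray(out, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(w) for w in self.items], columns=WORD_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WordList":
        items = []
        for i, row in enumerate(df.itertuples(index=False)):
            kwargs = {}
            for name in WORD_COLUMNS:
                value = getattr(row, name)
                if name in ("is_odor", "is_living", "is_food"):
                    value = bool(value)
                elif name == "syllables":
                    value = int(value)
                elif name != "label":
                    value = None if pd.isna(value) else float(value)
                kwargs[name] = value
            try:
                items.append(WordItem(**kwargs))
            except ValidationError as err:
                raise ValidationError(f"row {i}: {err}") from None
        return cls(items)


def load_word_list(path) -> WordList:
    """Read a word-property CSV (UTF-8, header row) into a validated WordList.

    Raises :class:`ValidationError` naming the offending row/column for
    duplicate labels, missing required columns, or out-of-range values.
    """
    df = pd.read_csv(path)
    missing = [c for c in WORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"word list {path}: missing columns {missing}")
    return WordList.from_frame(df)


# --------------------------------------------------------------------------
# packaged fixture
# --------------------------------------------------------------------------

# (mean, SD) per property for (odor-related, control) groups; n = 100 each.
_GROUP_MOMENTS = {
    "syllables": ((2.1, 0.9), (2.2, 0.6)),
    "frequency": ((4.9, 7.1), (6.1, 6.4)),
    "concreteness": ((6.7, 0.8), (6.8, 0.8)),
    "arousal": ((3.7, 0.8), (3.6, 0.9)),
    "imageability": ((6.5, 0.9), (6.6, 0.8)),
    "valence": ((5.4, 1.1), (5.3, 0.7)),
    "odor_rating": ((5.6, 1.8), (1.5, 0.5)),
}

# integer syllable-count compositions reproducing mean and (population) SD
_SYLLABLE_COUNTS = {
    True: [(1, 28), (2, 42), (3, 22), (4, 8)],  # mean 2.1, SD 0.90
    False: [(1, 10), (2, 60), (3, 30)],  # mean 2.2, SD 0.60
}


def _two_point(mean: float, sd: float, n: int) -> np.ndarray:
    """n values, half at mean-d and half at mean+d, with exact sample SD (ddof=1)."""
    d = sd * np.sqrt((n - 1) / n)
    half = n // 2
    return np.concatenate([np.full(half, mean - d), np.full(n - half, mean + d)])


def _skewed_two_point(mean: float, sd: float, n: int, frac_low: float = 0.9) -> np.ndarray:
    """Asymmetric two-point construction keeping the low value well above zero.

    ``frac_low`` of the values sit slightly below the mean and the rest sit
    correspondingly higher, preserving the exact sample mean and SD; used
    for the right-skewed frequency distribution, whose symmetric two-point
    encoding would produce negative occurrence rates.
    """
    n_low = int(round(frac_low * n))
    n_high = n - n_low
    # zero-mean pattern with unit sample variance: n_low at -a, n_high at b
    b_over_a = n_low / n_high
    a = np.sqrt((n - 1) / (n_low + n_high * b_over_a**2))
    values = np.concatenate(
        [np.full(n_low, mean - sd * a), np.full(n_high, mean + sd * a * b_over_a)]
    )
    return values


def build_matched_word_list(n_per_group: int = 100) -> WordList:
    """Construct the synthetic 200-word fixture with matched group moments.

    Deterministic (no randomness): property values per group are two-point
    or integer-composition constructions whose group means/SDs equal the
    target moments, so unpaired t-tests between groups reproduce the
    summary-statistic tests exactly (to within the integer constraint on
    syllable counts).  Category flags: 60% of odor words and 40% of control
    words are tagged living; 50% of odor words and 10% of control words are
    tagged food (food words are a subset of living words).
    """
    groups = {}
    for is_odor in (True, False):
        n = n_per_group
        cols: dict[str, np.ndarray] = {}
        for prop, (m_odor, m_ctrl) in _GROUP_MOMENTS.items():
            mean, sd = m_odor if is_odor else m_ctrl
            if prop == "syllables":
                vals = np.concatenate(
                    [np.full(cnt, k) for k, cnt in _SYLLABLE_COUNTS[is_odor]]
                )
                if len(vals) != n:  # scale compositions for non-default sizes
                    vals = np.resize(vals, n)
            elif prop == "frequency":
                vals = _skewed_two_point(mean, sd, n)
            else:
                vals = _two_point(mean, sd, n)
            cols[prop] = vals
        # interleave low/high halves so flag subsets are not property-confounded
        order = np.argsort(np.tile(np.arange((n + 1) // 2), 2)[:n], kind="stable")
        prefix = "odor" if is_odor else "control"
        items = []
        n_living = int(round((0.6 if is_odor else 0.4) * n))
        n_food = int(round((0.5 if is_odor else 0.1) * n))
        for rank, j in enumerate(order):
            items.append(
                WordItem(
                    label=f"{prefix}_{rank + 1:03d}",
                    is_odor=is_odor,
                    is_living=rank < n_living,
                    is_food=rank < n_food,
                    syllables=int(cols["syllables"][j]),
                    frequency=float(cols["frequency"][j]),
                    concreteness=float(cols["concreteness"][j]),
                    arousal=float(cols["arousal"][j]),
                    imageability=float(cols["imageability"][j]),
                    valence=float(cols["valence"][j]),
                    odor_rating=float(cols["odor_rating"][j]),
                )
            )
        groups[is_odor] = items
    return WordList(groups[True] + groups[False])


def default_word_list() -> WordList:
    """The packaged 200-word fixture (synthetic, moment-matched)."""
    path = resources.files("odorwords.data") / "word_properties.csv"
    with resources.as_file(path) as p:
        return load_word_list(p)


# --------------------------------------------------------------------------
# trial sequences
# --------------------------------------------------------------------------


def make_trial_sequence(
    words: WordList,
    n_once: int = 100,
    n_twice: int = 100,
    seed: int | np.random.Generator = 0,
    display_s: float = 0.5,
    jitter_range_s: tuple[float, float] = (1.7, 2.3),
    min_lag: int = 1,
    max_lag: int | None = None,
    slow_response_delay_s: float = 0.0,
    session_start_s: float = 2.0,
) -> pd.DataFrame:
    """Build a randomized continuous-recognition trial table.

    ``n_once`` words appear once and ``n_twice`` words twice, for a total of
    ``n_once + 2 * n_twice`` trials.  Word-to-group assignment and ordering
    are uniformly random given the seed; each repeat is inserted uniformly
    among the legal slots after its first presentation (at least ``min_lag``
    and at most ``max_lag`` positions later at insertion time).  Onsets
    advance by ``display_s`` plus a uniform jitter from ``jitter_range_s``
    (plus any modeled slow-response delay).

    Returns a DataFrame with columns :data:`TRIAL_COLUMNS`.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = [w.label for w in words.items]
    if n_once + n_twice > len(labels):
        raise ValidationError(
            f"need {n_once + n_twice} distinct words, have {len(labels)}"
        )
    if min_lag < 1:
        raise ValidationError("min_lag must be >= 1")
    perm = rng.permutation(len(labels))
    twice = [labels[i] for i in perm[:n_twice]]
    once = [labels[i] for i in perm[n_twice : n_twice + n_once]]

    seq = once + twice
    rng.shuffle(seq)
    for word in rng.permutation(twice):
        first = seq.index(word)
        lo = first + min_lag
        hi = len(seq) if max_lag is None else min(len(seq), first + max_lag)
        if lo > hi:
            lo = hi
        seq.insert(int(rng.integers(lo, hi + 1)), word)

    info = {w.label: w for w in words.items}
    seen: set[str] = set()
    rows = []
    onset = float(session_start_s)
    for i, word in enumerate(seq):
        w = info[word]
        presentation = 2 if word in seen else 1
        seen.add(word)
        rows.append(
            (i + 1, onset, word, w.is_odor, w.is_living, w.is_food, presentation)
        )
        onset += display_s + rng.uniform(*jitter_range_s) + slow_response_delay_s
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


# --------------------------------------------------------------------------
# word-property matching
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def summary_stat_ttest(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    welch: bool = False,
) -> TTestResult:
    """Two-sided unpaired t-test from group summary statistics.

    Default is the pooled-variance (Student) test with df = n1 + n2 - 2;
    ``welch=True`` uses the Welch statistic with Satterthwaite df.
    Degenerate inputs (both SDs zero) yield t = 0, p = 1 for equal means
    and p = 0 with a warning for unequal means.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if sd1 == 0.0 and sd2 == 0.0:
        if mean1 == mean2:
            return TTestResult(0.0, float(n1 + n2 - 2), 1.0)
        warnings.warn(
            "both groups have zero variance with unequal means; p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        t = np.inf if mean1 > mean2 else -np.inf
        return TTestResult(float(t), float(n1 + n2 - 2), 0.0)
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        t = (mean1 - mean2) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def compare_word_properties(words: WordList, welch: bool = False) -> pd.DataFrame:
    """Per-property unpaired t-tests between odor-related and control words.

    One two-sided test per matched property plus the odor-rating contrast,
    on raw item values and without multiplicity correction (a matching
    check, not inference).  Properties absent from both groups are flagged
    ``present=False`` rather than raising.
    """
    if words.n_odor == 0 or words.n_control == 0:
        raise ValidationError("both word categories must be non-empty")
    rows = []
    for prop in MATCHED_PROPERTIES + ("odor_rating",):
        a = words.values(prop, odor=True)
        b = words.values(prop, odor=False)
        if len(a) < 2 or len(b) < 2:
            rows.append((prop, np.nan, np.nan, np.nan, False))
            continue
        if np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0:
            res = summary_stat_ttest(a.mean(), 0.0, len(a), b.mean(), 0.0, len(b))
            t, df, p = res.t, res.df, res.p
        else:
            res = stats.ttest_ind(a, b, equal_var=not welch)
            t, p, df = res.statistic, res.pvalue, res.df
        rows.append((prop, float(t), float(df), float(p), True))
    return pd.DataFrame(rows, columns=["property", "t", "df", "p", "present"])
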