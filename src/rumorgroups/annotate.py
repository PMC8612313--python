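"""Group-level annotation: COVID keyword tagging, script-origin flags,
contingency tables and the Yates-corrected chi-square test.

Keyword tagging runs on the raw message text (before the character filter —
several keywords are latin strings the filter would delete) and promotes a
group to *candidate* status when strictly more than 60% of its messages
contain a keyword; candidates still require a human decision, and once
confirmed every member message inherits COVID-relatedness. The script-origin
flag marks messages containing simplified-only characters or mainland-usage
phrases; crossing the two annotations yields a 2×2 contingency table tested
with the chi-square independence test with Yates' continuity correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cluster_engine import Labeling
from .lexicons import KeywordLexicon, ScriptLexicon

__all__ = [
    "ContingencyTable2x2",
    "message_has_keyword",
    "flag_covid_groups",
    "confirm_covid_groups",
    "flag_script_origin",
    "contingency_from_flags",
    "chi_square_yates",
    "format_p_value",
    "percent_of",
    "group_size_stats",
    "GroupSizeStats",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = COVID-related yes/no, cols = script-flagged yes/no."""

    a: int  # related, flagged
    b: int  # related, not flagged
    c: int  # not related, flagged
    d: int  # not related, not flagged

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def message_has_keyword(text: str, lexicon: KeywordLexicon) -> bool:
    """True iff any lexicon term occurs case-insensitively in the raw text."""
    if not text:
        return False
    lowered = text.lower()
    return any(term in lowered for term in lexicon.terms)


def flag_covid_groups(
    labeling: Labeling,
    texts: Sequence[str],
    lexicon: KeywordLexicon,
    threshold: float = 0.60,
) -> pd.DataFrame:
    """Per-group keyword fraction and candidate flag (strict > threshold).

    The returned ``status`` column is "candidate — requires manual
    confirmation" for flagged groups: automation only shortlists; the final
    COVID-relatedness call is a human adjudication step (see
    :func:`confirm_covid_groups`).
    """
    if len(texts) != len(labeling):
        raise ValueError("texts must align with the labeling")
    hits = np.fromiter(
        (message_has_keyword(t, lexicon) for t in texts), dtype=bool, count=len(texts)
    )
    frame = pd.DataFrame({"group_id": labeling.labels, "hit": hits})
    agg = frame.groupby("group_id").agg(size=("hit", "size"), n_keyword=("hit", "sum"))
    agg["keyword_fraction"] = agg["n_keyword"] / agg["size"]
    agg["covid_candidate"] = agg["keyword_fraction"] > threshold
    agg["status"] = np.where(
        agg["covid_candidate"], "candidate — requires manual confirmation", "not a candidate"
    )
    return agg.reset_index()


def confirm_covid_groups(
    labeling: Labeling, confirmed_group_ids: Iterable[int]
) -> np.ndarray:
    """Propagate a confirmed group decision to every member message."""
    confirmed = set(int(g) for g in confirmed_group_ids)
    return np.isin(labeling.labels, list(confirmed))


def flag_script_origin(text: str, lexicon: ScriptLexicon) -> bool:
    """True iff the text contains a simplified-only character or a phrase."""
    if not text:
        return False
    if any(ch in lexicon.simplified_only_chars for ch in text):
        return True
    return any(phrase in text for phrase in lexicon.phrases)


def contingency_from_flags(
    covid_related: Sequence[bool], script_flagged: Sequence[bool]
) -> ContingencyTable2x2:
    covid = np.asarray(covid_related, dtype=bool)
    script = np.asarray(script_flagged, dtype=bool)
    if covid.shape != script.shape:
        raise ValueError("flag vectors must align")
    return ContingencyTable2x2(
        a=int((covid & script).sum()),
        b=int((covid & ~script).sum()),
        c=int((~covid & script).sum()),
        d=int((~covid & ~script).sum()),
    )


def chi_square_yates(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Chi-square independence test with Yates' continuity correction.

    statistic = n (|ad − bc| − n/2)² / ((a+b)(c+d)(a+c)(b+d)), clamped to 0
    when |ad − bc| ≤ n/2; the p-value comes from the chi-square distribution
    with 1 degree of freedom. Returns (statistic, df, p_value).
    """
    r1, r2, c1, c2 = table.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("all margins must be positive for the test")
    n = table.n
    diff = abs(table.a * table.d - table.b * table.c)
    corrected = diff - n / 2
    if corrected <= 0:
        stat = 0.0
    else:
        stat = n * corrected**2 / (r1 * r2 * c1 * c2)
    return float(stat), 1, float(chi2.sf(stat, df=1))


def format_p_value(p: float) -> str:
    """Report tiny p-values as "<.001" in the conventional style."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0") or ".000"


def percent_of(part: int, whole: int) -> float:
    """100·part/whole, rounded half-up to one decimal (table style)."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    value = Decimal(100 * part) / Decimal(whole)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GroupSizeStats:
    n_groups: int
    mean: float
    sd: float
    max: int
    q1: float
    median: float
    q3: float
    total: int

    @property
    def empty(self) -> bool:
        return self.n_groups == 0


_EMPTY_STATS = GroupSizeStats(0, float("nan"), float("nan"), 0, float("nan"),
                              float("nan"), float("nan"), 0)


def group_size_stats(labeling: Labeling, min_size: int = 1) -> GroupSizeStats:
    """Summary statistics over the multiset of group sizes ≥ ``min_size``.

    Quartiles use linear interpolation; the standard deviation is the sample
    (ddof=1) estimate. Returns an empty-stats marker when no group qualifies.
    """
    sizes = np.array(sorted(labeling.group_sizes().values()), dtype=float)
    sizes = sizes[sizes >= min_size]
    if sizes.size == 0:
        return _EMPTY_STATS
    q1, med, q3 = np.percentile(sizes, [25, 50, 75], method="linear")
    sd = float(np.std(sizes, ddof=1)) if sizes.size > 1 else 0.0
    return GroupSizeStats(
        n_groups=int(sizes.size),
        mean=float(sizes.mean()),
        sd=sd,
        max=int(sizes.max()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        total=int(sizes.sum()),
    )
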