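"""Seeded synthetic message corpora with planted rumor groups.

The generator emulates the statistical shape the pipeline assumes about a
reported-message corpus: a long-tailed (Zipf) group-size distribution, each
group a cloud of near-duplicate variants of a distinct token template,
singleton noise messages unrelated to everything, occasional composite
messages concatenating two rumor templates, bursty report dates (each group
goes viral one to a few times), and simplified-script markers planted at a
known rate. Tokens are synthetic symbols (``w000123``) separated by spaces,
so generator correctness never depends on a Chinese segmenter dictionary;
script markers are real simplified-only characters so the script-origin
annotator has planted ground truth.

Every draw flows from one seeded generator: identical spec + seed ⇒
identical corpus.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lexicons import load_script_lexicon

__all__ = ["SynthSpec", "SynthCorpus", "SeparationBounds", "generate_corpus",
           "expected_separation", "write_corpus", "MIXED_LABEL"]

#: Ground-truth label of composite (two-template) messages; they have no
#: single planted group and are excluded from planted-partition scoring.
MIXED_LABEL = -2


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class SynthSpec:
    """Conditions of a synthetic corpus.

    Defaults describe a small but realistically shaped corpus: Zipf
    (rank-frequency, exponent 1) group sizes, 30-token templates — long
    enough to survive the default 20-token length filter with room for
    deletions — a 5% per-token mutation rate giving within-group distances
    around 0.07 against between-group distances of 1, singleton noise at
    roughly 7.5% of messages and a handful of composite messages.
    """

    n_groups: int = 50
    size_distribution: str = "power_law"  # or "fixed"
    fixed_size: int = 20
    power_exponent: float = 1.0
    n_group_messages: int = 1000  # total messages across groups (power_law)
    template_length: int = 30
    mutation_rate: float = 0.05
    n_singletons: int = 75
    combined_pairs: int = 5
    burst_spec: Optional[Sequence[tuple]] = None  # (group, center, spread_days, weight)
    script_marker_rate: float = 0.1
    vocab_size: Optional[int] = None  # auto: enough for disjoint templates
    start_date: str = "2020-01-22"
    end_date: str = "2020-07-31"
    seed: int = 0

    def __post_init__(self):
        if self.size_distribution not in ("power_law", "fixed"):
            raise SpecError("size_distribution must be 'power_law' or 'fixed'")
        for name in ("mutation_rate", "script_marker_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} must be in [0, 1]")
        if self.template_length < 20:
            raise SpecError("template_length must be >= 20 so variants survive the length filter")
        if self.n_groups < 1:
            raise SpecError("need at least one group")
        needed = self.n_groups * self.template_length
        if self.vocab_size is not None and self.vocab_size < needed:
            raise SpecError(
                f"vocab_size {self.vocab_size} cannot keep {self.n_groups} "
                f"templates of {self.template_length} tokens disjoint (need {needed})"
            )

    @property
    def total_group_messages(self) -> int:
        if self.size_distribution == "fixed":
            return self.n_groups * self.fixed_size
        return self.n_group_messages

    @property
    def total_messages(self) -> int:
        return self.total_group_messages + self.n_singletons + self.combined_pairs


@dataclass(frozen=True)
class SynthCorpus:
    messages: pd.DataFrame  # message_id, report_timestamp, user_hash, text
    truth: pd.DataFrame  # message_id, group, is_mixed, is_singleton, script_marker
    spec: SynthSpec

    @property
    def truth_labels(self) -> np.ndarray:
        return self.truth["group"].to_numpy()


def _group_sizes(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.size_distribution == "fixed":
        return np.full(spec.n_groups, spec.fixed_size, dtype=np.int64)
    ranks = np.arange(1, spec.n_groups + 1, dtype=np.float64)
    p = ranks**-spec.power_exponent
    p /= p.sum()
    return rng.multinomial(spec.n_group_messages, p)


def _mutate(template: Sequence[str], rate: float, rng: np.random.Generator,
            fresh) -> list[str]:
    """Per-token substitute/insert/delete at the given rate; noise tokens are
    fresh symbols so two variants only ever share unmutated template tokens."""
    out: list[str] = []
    for tok in template:
        if rng.random() >= rate:
            out.append(tok)
            continue
        op = rng.integers(3)
        if op == 0:  # substitute
            out.append(fresh())
        elif op == 1:  # insert (keep token, add noise after)
            out.append(tok)
            out.append(fresh())
        # op == 2: delete
    return out if out else [fresh()]


def _default_bursts(spec: SynthSpec, n_days: int, rng: np.random.Generator):
    """1–4 report-date bursts per group: center day, spread (days), weight."""
    bursts = {}
    for g in range(spec.n_groups):
        k = int(rng.integers(1, 5))
        centers = rng.integers(0, n_days, size=k)
        spreads = rng.uniform(0.5, 3.0, size=k)
        weights = rng.dirichlet(np.ones(k))
        bursts[g] = list(zip(centers.tolist(), spreads.tolist(), weights.tolist()))
    return bursts


def _parse_burst_spec(spec: SynthSpec, start: pd.Timestamp, n_days: int):
    bursts: dict[int, list[tuple]] = {}
    for group, center, spread, weight in spec.burst_spec:  # type: ignore[union-attr]
        day = int((pd.Timestamp(center) - start).days)
        bursts.setdefault(int(group), []).append((day, float(spread), float(weight)))
    for g, entries in bursts.items():
        total = sum(w for _, _, w in entries)
        bursts[g] = [(d, s, w / total) for d, s, w in entries]
    return bursts


def _stamp(day: int, n_days: int, start: pd.Timestamp, rng: np.random.Generator) -> str:
    day = int(np.clip(day, 0, n_days - 1))
    seconds = int(rng.integers(0, 86400))
    ts = start + pd.Timedelta(days=day, seconds=seconds)
    return ts.isoformat() + "+08:00"


def generate_corpus(spec: SynthSpec) -> SynthCorpus:
    """Generate (messages, ground-truth labeling, annotations) for a spec."""
    rng = np.random.default_rng(spec.seed)
    start = pd.Timestamp(spec.start_date)
    n_days = int((pd.Timestamp(spec.end_date) - start).days) + 1
    if n_days < 1:
        raise SpecError("end_date must not precede start_date")

    sizes = _group_sizes(spec, rng)
    templates = [
        [f"w{g * spec.template_length + j:06d}" for j in range(spec.template_length)]
        for g in range(spec.n_groups)
    ]
    marker_chars = sorted(load_script_lexicon().simplified_only_chars)

    if spec.burst_spec is not None:
        bursts = _parse_burst_spec(spec, start, n_days)
    else:
        bursts = _default_bursts(spec, n_days, rng)

    counters = {g: 0 for g in range(spec.n_groups)}

    def fresh_factory(g):
        def fresh():
            counters[g] += 1
            return f"g{g}x{counters[g]:06d}"

        return fresh

    def group_day(g):
        entries = bursts.get(g)
        if not entries:
            return int(rng.integers(0, n_days))
        idx = rng.choice(len(entries), p=[w for _, _, w in entries])
        day, spread, _ = entries[idx]
        return int(round(rng.normal(day, spread)))

    rows, truth_rows = [], []
    counter = 0

    def emit(tokens, group, day, is_mixed=False, is_singleton=False):
        nonlocal counter
        marked = rng.random() < spec.script_marker_rate
        text = " ".join(tokens)
        if marked:
            picks = rng.choice(len(marker_chars), size=int(rng.integers(1, 4)), replace=False)
            text = text + " " + " ".join(marker_chars[i] for i in picks)
        mid = f"m{counter:06d}"
        counter += 1
        rows.append(
            {
                "message_id": mid,
                "report_timestamp": _stamp(day, n_days, start, rng),
                "user_hash": f"u{rng.integers(0, 10**9):09d}",
                "text": text,
            }
        )
        truth_rows.append(
            {
                "message_id": mid,
                "group": group,
                "is_mixed": is_mixed,
                "is_singleton": is_singleton,
                "script_marker": marked,
            }
        )

    for g in range(spec.n_groups):
        fresh = fresh_factory(g)
        for _ in range(int(sizes[g])):
            emit(_mutate(templates[g], spec.mutation_rate, rng, fresh), g, group_day(g))

    for s in range(spec.n_singletons):
        tokens = [f"s{s:05d}t{j:03d}" for j in range(spec.template_length)]
        emit(tokens, spec.n_groups + s, int(rng.integers(0, n_days)), is_singleton=True)

    nonzero = np.flatnonzero(sizes >= 1)
    for _ in range(spec.combined_pairs):
        if len(nonzero) < 2:
            raise SpecError("combined messages need at least two non-empty groups")
        ga, gb = rng.choice(nonzero, size=2, replace=False)
        tokens = _mutate(templates[ga], spec.mutation_rate, rng, fresh_factory(int(ga))) + \
            _mutate(templates[gb], spec.mutation_rate, rng, fresh_factory(int(gb)))
        emit(tokens, MIXED_LABEL, group_day(int(ga)), is_mixed=True)

    order = rng.permutation(len(rows))
    messages = pd.DataFrame(rows).iloc[order].reset_index(drop=True)
    truth = pd.DataFrame(truth_rows).iloc[order].reset_index(drop=True)
    return SynthCorpus(messages=messages, truth=truth, spec=spec)


@dataclass(frozen=True)
class SeparationBounds:
    """Analytic within/between distance expectations for a spec.

    A template token survives unmutated in one variant with probability
    s = 1 − 2·rate/3 (substitution and deletion remove it; insertion keeps
    it), so two independent variants of a template of length T share ≈ T·s²
    tokens while each keeps an expected T tokens, giving an expected
    within-group distance of 1 − s². The convenient looser bound 2·rate is
    reported alongside. Disjoint templates with fresh noise tokens put
    between-group distances at exactly 1.
    """

    expected_within: float
    within_bound: float
    between: float


def expected_separation(spec: SynthSpec) -> SeparationBounds:
    m = spec.mutation_rate
    if m >= 0.5:
        raise SpecError("separation bounds assume mutation_rate < 0.5")
    s = 1.0 - 2.0 * m / 3.0
    return SeparationBounds(
        expected_within=1.0 - s * s,
        within_bound=2.0 * m,
        between=1.0,
    )


def write_corpus(corpus: SynthCorpus, outdir) -> dict[str, Path]:
    """Write messages.csv, truth.csv and a spec-echo JSON for provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "messages": outdir / "messages.csv",
        "truth": outdir / "truth.csv",
        "spec": outdir / "spec.json",
    }
    corpus.messages.to_csv(paths["messages"], index=False)
    corpus.truth.to_csv(paths["truth"], index=False)
    spec_dict = dataclasses.asdict(corpus.spec)
    if spec_dict["burst_spec"] is not None:
        spec_dict["burst_spec"] = [list(b) for b in spec_dict["burst_spec"]]
    paths["spec"].write_text(json.dumps(spec_dict, indent=2, default=str), encoding="utf-8")
    return paths
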