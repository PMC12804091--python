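"""Cohort stratification: activating mutations, copy-number gain, co-occurrence.

A tumour is *CTNNB1*-activated when it carries a missense mutation at one of
the canonical exon-3/armadillo hotspot residues (32, 33, 34, 35, 36, 37, 41,
45, 335, 383, 387) or an in-frame indel touching residues 23-71. Copy gain
for a query gene (typically *MYC*) is a GISTIC call of +1 (gain) or +2
(high-level amplification). The co-occurrence summary reports the fraction
of activated tumours with copy gain and contrasts expression, on the
log2(RSEM + 1) scale, between gain and no-gain and between activated and
non-activated tumours with a two-sided Student's t-test (equal-variance by
default; Welch optional).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .catalog_io import CohortTable, MutationRecord, VariantClass
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ActivatingRule",
    "GroupStats",
    "CooccurrenceSummary",
    "classify_ctnnb1_activating",
    "classify_cna_gain",
    "cooccurrence_summary",
]

DEFAULT_HOTSPOTS = frozenset({32, 33, 34, 35, 36, 37, 41, 45, 335, 383, 387})
DEFAULT_INDEL_RANGE = (23, 71)


@dataclass(frozen=True)
class ActivatingRule:
    hotspot_positions: frozenset[int] = DEFAULT_HOTSPOTS
    indel_range: tuple[int, int] = DEFAULT_INDEL_RANGE

    def __post_init__(self):
        object.__setattr__(self, "hotspot_positions", frozenset(self.hotspot_positions))
        start, end = self.indel_range
        if start > end:
            raise ValidationError(f"indel range {start}-{end} has start > end")


def classify_ctnnb1_activating(
    mutations: list[MutationRecord], rule: ActivatingRule = ActivatingRule()
) -> bool:
    """True iff any record is a hotspot missense or an in-frame indel
    whose residue range intersects the hotspot interval."""
    lo, hi = rule.indel_range
    for rec in mutations:
        if rec.protein_pos is None:
            logger.warning(
                "record %s %s:%d lacks protein position; skipped by classifier",
                rec.sample_id,
                rec.chrom,
                rec.pos,
            )
            continue
        if rec.variant_class is VariantClass.MISSENSE:
            if rec.protein_start in rule.hotspot_positions:
                return True
        elif rec.variant_class is VariantClass.IN_FRAME_INDEL:
            start, end = rec.protein_range
            if start <= hi and end >= lo:
                return True
    return False


def classify_cna_gain(gistic_call: int, threshold: int = 1) -> bool:
    """True for GISTIC +1 (gain) or +2 (high-level amplification)."""
    if gistic_call not in {-2, -1, 0, 1, 2}:
        raise ValidationError(f"GISTIC call {gistic_call} outside -2..2")
    return gistic_call >= threshold


@dataclass
class GroupStats:
    n: int
    mean: float
    sd: float


@dataclass
class TTestResult:
    contrast: str
    t_statistic: float | None
    p_value: float | None
    skipped_reason: str | None = None


@dataclass
class CooccurrenceSummary:
    n_total: int
    n_excluded: int
    n_activated: int
    n_activated_with_gain: int
    proportion_gain: float
    expression_group_stats: dict[str, GroupStats] = field(default_factory=dict)
    t_tests: list[TTestResult] = field(default_factory=list)

    def __post_init__(self):
        assert self.n_activated_with_gain <= self.n_activated


def _group_stats(values: np.ndarray) -> GroupStats:
    return GroupStats(
        n=len(values),
        mean=float(np.mean(values)) if len(values) else float("nan"),
        sd=float(np.std(values, ddof=1)) if len(values) > 1 else float("nan"),
    )


def _ttest(name: str, a: np.ndarray, b: np.ndarray, welch: bool) -> TTestResult:
    if len(a) < 2 or len(b) < 2:
        return TTestResult(
            contrast=name,
            t_statistic=None,
            p_value=None,
            skipped_reason=f"a group has fewer than 2 samples (n={len(a)}, {len(b)})",
        )
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(contrast=name, t_statistic=float(t), p_value=float(p))


def cooccurrence_summary(
    cohort: CohortTable,
    rule: ActivatingRule = ActivatingRule(),
    gain_threshold: int = 1,
    welch: bool = False,
) -> CooccurrenceSummary:
    """Fraction of activated tumours with copy gain, plus expression contrasts.

    Excluded samples (e.g. mismatch-repair deficient) are dropped first.
    The denominator of ``proportion_gain`` is every non-excluded activated
    tumour and is reported explicitly as ``n_activated``.
    """
    df = cohort.active_samples().copy()
    df["activated"] = [
        classify_ctnnb1_activating(cohort.mutations.get(s, []), rule)
        for s in df["sample_id"]
    ]
    df["gain"] = [classify_cna_gain(c, gain_threshold) for c in df["gistic_call"]]

    activated = df[df["activated"]]
    n_activated = len(activated)
    n_gain = int(activated["gain"].sum())
    proportion = n_gain / n_activated if n_activated else float("nan")

    expr = df["log2_expression"].to_numpy()
    groups = {
        "gain": expr[df["gain"].to_numpy()],
        "no_gain": expr[~df["gain"].to_numpy()],
        "activated": expr[df["activated"].to_numpy()],
        "not_activated": expr[~df["activated"].to_numpy()],
    }
    tests = [
        _ttest("gain_vs_no_gain", groups["gain"], groups["no_gain"], welch),
        _ttest("activated_vs_not", groups["activated"], groups["not_activated"], welch),
    ]
    return CooccurrenceSummary(
        n_total=len(cohort.table),
        n_excluded=int(cohort.table["excluded"].sum()),
        n_activated=n_activated,
        n_activated_with_gain=n_gain,
        proportion_gain=proportion,
        expression_group_stats={k: _group_stats(v) for k, v in groups.items()},
        t_tests=tests,
    )


def cbioportal_cooccurrence(
    mutations_path,
    cna_path,
    gene: str = "CTNNB1",
    cna_gene: str = "MYC",
    exclude_samples: set[str] | None = None,
    rule: ActivatingRule = ActivatingRule(),
    gain_threshold: int = 1,
) -> tuple[int, int, float]:
    """Co-occurrence from cBioPortal study files.

    ``mutations_path`` is a MAF-dialect ``data_mutations.txt``;
    ``cna_path`` a discrete GISTIC matrix (``data_cna.txt``: Hugo_Symbol
    column, one column per sample). Samples without a CNA call for
    ``cna_gene`` are dropped from the denominator. Returns
    ``(n_activated, n_activated_with_gain, proportion)``.
    """
    import pandas as pd

    from .catalog_io import read_mutation_catalog

    exclude = exclude_samples or set()
    records = read_mutation_catalog(mutations_path, dialect="maf")
    by_sample: dict[str, list[MutationRecord]] = {}
    for rec in records:
        if rec.gene == gene and rec.sample_id not in exclude:
            by_sample.setdefault(rec.sample_id, []).append(rec)

    cna = pd.read_csv(cna_path, sep="\t", comment="#")
    row = cna[cna["Hugo_Symbol"] == cna_gene]
    if row.empty:
        raise ValidationError(f"{cna_gene} not found in {cna_path}")
    calls = row.iloc[0].drop(
        labels=[c for c in ("Hugo_Symbol", "Entrez_Gene_Id") if c in cna.columns]
    )

    n_activated = n_gain = 0
    for sample, muts in by_sample.items():
        if sample not in calls.index or pd.isna(calls[sample]):
            continue
        if classify_ctnnb1_activating(muts, rule):
            n_activated += 1
            if classify_cna_gain(int(calls[sample]), gain_threshold):
                n_gain += 1
    proportion = n_gain / n_activated if n_activated else float("nan")
    return n_activated, n_gain, proportion
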