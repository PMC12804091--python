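"""Expected per-codon missense mutation frequency under background mutation.

Given a gene-local channel distribution P_i (the exome-wide spectrum
renormalized to the gene's trinucleotide composition) the expected missense
frequency at protein position p is

    predicted[p] = sum_i P_i * m_{p,i} / N[c(i)]

where m_{p,i} is the number of (site, alternate-base) pairs in codon p whose
substitution classifies to channel i and changes the amino acid (not to a
stop), N[c] is the number of gene sites carrying the channel's source
trinucleotide context c(i), and the division realizes the assumption that a
type-i mutation lands uniformly among the gene's sites with that context.
The predicted profile is then scaled so its sum matches the observed
missense count, and positions are ranked by observed/predicted excess.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog_io import GeneModel, MutationRecord, VariantClass
from .errors import DataError, DegenerateModelError
from .spectrum import (
    CHANNEL_CONTEXT_INDEX,
    LocalSpectrum,
    classify_channel,
    context_composition,
)

__all__ = [
    "CODON_TO_AA",
    "Consequence",
    "CodonSiteTable",
    "ObservedPositionCounts",
    "PositionExpectation",
    "build_codon_site_table",
    "expected_missense_profile",
    "observed_position_counts",
    "normalize_to_observed",
    "hotspot_excess_report",
]


def _standard_codon_table() -> dict[str, str]:
    from Bio.Seq import Seq

    bases = "ACGT"
    return {
        a + b + c: str(Seq(a + b + c).translate())
        for a in bases
        for b in bases
        for c in bases
    }


CODON_TO_AA = _standard_codon_table()

# consequence codes stored in the site table
MISSENSE, SYNONYMOUS, NONSENSE, STOP_LOST = 0, 1, 2, 3
Consequence = {MISSENSE: "missense", SYNONYMOUS: "synonymous", NONSENSE: "nonsense", STOP_LOST: "stop_lost"}


@dataclass
class CodonSiteTable:
    """Per (protein position, CDS site, alternate base): channel and consequence.

    ``channel[p, s, a]`` is the 0-based channel index for residue ``p+1``,
    codon site ``s`` (0..2) and the ``a``-th alternate base (the three bases
    other than the reference, in ACGT order); ``consequence`` holds the
    matching consequence code. ``context_counts[c]`` is the number of CDS
    sites whose pyrimidine-collapsed context is ``c`` (sums to 3L).
    """

    gene: str
    protein_length: int
    channel: np.ndarray  # (L, 3, 3) int
    consequence: np.ndarray  # (L, 3, 3) int
    context_counts: np.ndarray  # (32,) int


def build_codon_site_table(gene: GeneModel) -> CodonSiteTable:
    """Enumerate all 9 single-base substitutions of every codon.

    Contexts at codon boundaries come from the flanked coding-strand
    sequence, so the first and last CDS positions are classifiable.
    """
    seq = gene.cds_with_flanks
    L = gene.protein_length
    channel = np.zeros((L, 3, 3), dtype=np.int64)
    consequence = np.zeros((L, 3, 3), dtype=np.int64)
    for p in range(L):
        codon = seq[1 + 3 * p : 4 + 3 * p]
        aa_ref = CODON_TO_AA[codon]
        for s in range(3):
            cds_pos = 3 * p + s + 1  # 1-based CDS position
            ref = seq[cds_pos]
            flank5, flank3 = seq[cds_pos - 1], seq[cds_pos + 1]
            alts = [b for b in "ACGT" if b != ref]
            for a, alt in enumerate(alts):
                ch = classify_channel(ref, alt, flank5, flank3)
                mutant = codon[:s] + alt + codon[s + 1 :]
                aa_alt = CODON_TO_AA[mutant]
                if aa_alt == aa_ref:
                    cons = SYNONYMOUS
                elif aa_alt == "*":
                    cons = NONSENSE
                elif aa_ref == "*":
                    cons = STOP_LOST
                else:
                    cons = MISSENSE
                channel[p, s, a] = ch.index
                consequence[p, s, a] = cons
    ctx = context_composition(gene)
    return CodonSiteTable(
        gene=gene.gene,
        protein_length=L,
        channel=channel,
        consequence=consequence,
        context_counts=ctx.counts,
    )


def expected_missense_profile(local: LocalSpectrum, table: CodonSiteTable) -> np.ndarray:
    """Unnormalized predicted missense frequency per protein position.

    Channels whose source context is absent from the gene contribute
    nothing (their local probability is zero by construction).
    """
    L = table.protein_length
    n_ctx = table.context_counts.astype(float)
    probs = local.probs
    ctx_of_channel = CHANNEL_CONTEXT_INDEX
    predicted = np.zeros(L)
    missense_mask = table.consequence == MISSENSE
    for p in range(L):
        chans = table.channel[p][missense_mask[p]]
        if chans.size == 0:
            continue
        denom = n_ctx[ctx_of_channel[chans]]
        ok = denom > 0
        if probs[chans[~ok]].any():
            raise DataError(
                "local spectrum assigns probability to a context absent from the "
                "gene; were the spectrum and site table built from the same gene?"
            )
        predicted[p] = np.sum(probs[chans[ok]] / denom[ok])
    return predicted


@dataclass
class ObservedPositionCounts:
    """Missense SNV counts per residue, pooled across input catalogues."""

    gene: str
    counts: np.ndarray
    n_skipped: int = 0  # missense records without usable protein position

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)


def observed_position_counts(
    records: list[MutationRecord], gene: GeneModel
) -> ObservedPositionCounts:
    """Tally missense SNVs of the focal gene by 1-based residue."""
    counts = np.zeros(gene.protein_length, dtype=np.int64)
    skipped = 0
    for rec in records:
        if rec.gene != gene.gene or rec.variant_class is not VariantClass.MISSENSE:
            continue
        if not rec.is_snv:
            continue
        p = rec.protein_start
        if p is None or not (1 <= p <= gene.protein_length):
            skipped += 1
            continue
        counts[p - 1] += 1
    return ObservedPositionCounts(gene=gene.gene, counts=counts, n_skipped=skipped)


@dataclass
class PositionExpectation:
    """Predicted (scaled to the observed total) vs observed per residue.

    ``ratio[p]`` is observed/predicted, with ``inf`` where the model
    predicts zero but mutations were observed and ``0`` where both are zero.
    """

    gene: str
    predicted: np.ndarray
    observed: np.ndarray
    ratio: np.ndarray = field(init=False)

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.observed = np.asarray(self.observed, dtype=np.int64)
        if self.predicted.shape != self.observed.shape:
            raise DataError("predicted and observed lengths differ")
        ratio = np.zeros_like(self.predicted)
        nz = self.predicted > 0
        ratio[nz] = self.observed[nz] / self.predicted[nz]
        ratio[~nz & (self.observed > 0)] = np.inf
        self.ratio = ratio


def normalize_to_observed(
    predicted: np.ndarray, observed: ObservedPositionCounts
) -> PositionExpectation:
    """Scale the predicted profile so its sum equals the observed total."""
    predicted = np.asarray(predicted, dtype=float)
    total_pred = predicted.sum()
    if total_pred <= 0:
        raise DegenerateModelError("predicted profile sums to zero")
    scale = observed.counts.sum() / total_pred
    return PositionExpectation(
        gene=observed.gene, predicted=predicted * scale, observed=observed.counts
    )


def hotspot_excess_report(pe: PositionExpectation, top_k: int | None = None) -> pd.DataFrame:
    """Residues ranked by observed/predicted excess.

    Ties are broken by observed count, then by position. The Poisson
    upper-tail p-value (mean = predicted) is a descriptive convenience,
    not a calibrated hotspot test.
    """
    L = len(pe.predicted)
    df = pd.DataFrame(
        {
            "position": np.arange(1, L + 1),
            "observed": pe.observed,
            "predicted": pe.predicted,
            "ratio": pe.ratio,
            "p_poisson": stats.poisson.sf(pe.observed - 1, mu=pe.predicted),
        }
    )
    df = df.sort_values(
        ["ratio", "observed", "position"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, L + 1)
    if top_k is not None:
        df = df.head(top_k)
    return df
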