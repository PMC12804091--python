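"""The 96-channel trinucleotide mutational spectrum.

Single-nucleotide variants are classified into 96 channels: 6 substitution
classes (C>A, C>G, C>T, T>A, T>C, T>G, after collapsing purine-reference
changes onto the pyrimidine strand) x 4 possible 5' flanking bases x 4
possible 3' flanking bases. Channel order is the conventional lexicographic
one (substitution class major, then 5' flank, then 3' flank), so channel 0
is ``A[C>A]A`` and channel 95 is ``T[T>G]T``.

The cohort-level spectrum is the mean of per-sample *proportions* (each
tumour weighted equally, which keeps hypermutators from dominating); a
pooled-count alternative is available. The exome-wide spectrum is carried
to a gene by reweighting each channel with the ratio of the gene's to the
exome's trinucleotide-context frequencies and renormalizing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .catalog_io import GeneModel, MutationRecord
from .errors import DataError, DegenerateModelError, EmptyInputError, ReferenceMismatchError

logger = logging.getLogger(__name__)

__all__ = [
    "SUBSTITUTIONS",
    "BASES",
    "CHANNELS",
    "CONTEXTS",
    "MutationChannel",
    "SampleSpectrum",
    "CohortSpectrum",
    "ContextComposition",
    "LocalSpectrum",
    "classify_channel",
    "channel_context",
    "SequenceContext",
    "sample_spectra",
    "mean_spectrum",
    "context_composition",
    "renormalize_to_gene",
]

BASES = "ACGT"
SUBSTITUTIONS = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MutationChannel:
    index: int
    label: str  # e.g. "A[C>T]G"

    @property
    def ref(self) -> str:
        return self.label[2]

    @property
    def alt(self) -> str:
        return self.label[4]

    @property
    def flank5(self) -> str:
        return self.label[0]

    @property
    def flank3(self) -> str:
        return self.label[6]

    @property
    def context(self) -> str:
        """Pyrimidine-centric source trinucleotide, e.g. ``ACG``."""
        return self.flank5 + self.ref + self.flank3


def _build_channels() -> list[MutationChannel]:
    channels = []
    for ref, alt in SUBSTITUTIONS:
        for f5 in BASES:
            for f3 in BASES:
                channels.append(
                    MutationChannel(len(channels), f"{f5}[{ref}>{alt}]{f3}")
                )
    return channels


#: The 96 channels in canonical order.
CHANNELS: list[MutationChannel] = _build_channels()
_CHANNEL_BY_LABEL = {c.label: c for c in CHANNELS}

#: The 32 pyrimidine-centric trinucleotide contexts, in the order implied by
#: the channel layout (context of channel i is CONTEXTS[...]).
CONTEXTS: list[str] = [f5 + ref + f3 for ref in "CT" for f5 in BASES for f3 in BASES]
_CONTEXT_INDEX = {ctx: i for i, ctx in enumerate(CONTEXTS)}

#: context index of each channel (length 96)
CHANNEL_CONTEXT_INDEX = np.array([_CONTEXT_INDEX[c.context] for c in CHANNELS])


def channel_context(channel: MutationChannel | int) -> int:
    """Index (0..31) of a channel's source context."""
    if isinstance(channel, MutationChannel):
        channel = channel.index
    return int(CHANNEL_CONTEXT_INDEX[channel])


def classify_channel(ref: str, alt: str, flank5: str, flank3: str) -> MutationChannel:
    """Map an SNV with its immediate flanks onto one of the 96 channels.

    Purine-reference changes are reverse-complemented onto the pyrimidine
    strand first, so classification is strand-symmetric.
    """
    ref, alt, flank5, flank3 = (b.upper() for b in (ref, alt, flank5, flank3))
    for b in (ref, alt, flank5, flank3):
        if b not in BASES:
            raise DataError(f"ambiguous or invalid base {b!r} in SNV context")
    if ref == alt:
        raise DataError("ref == alt is not a substitution")
    if ref in "AG":  # purine reference: collapse to the pyrimidine strand
        flank5, ref, flank3 = revcomp(flank5 + ref + flank3)
        alt = revcomp(alt)
    return _CHANNEL_BY_LABEL[f"{flank5}[{ref}>{alt}]{flank3}"]


@dataclass
class SampleSpectrum:
    sample_id: str
    counts: np.ndarray  # 96 nonnegative ints
    total_snvs: int = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise DataError("sample spectrum must have 96 channels")
        self.total_snvs = int(self.counts.sum())

    def proportions(self) -> np.ndarray:
        if self.total_snvs == 0:
            raise EmptyInputError(f"sample {self.sample_id} has no classified SNVs")
        return self.counts / self.total_snvs


@dataclass
class CohortSpectrum:
    """The exome-wide per-channel mutation probability (sums to 1)."""

    probs: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (96,):
            raise DataError("cohort spectrum must have 96 channels")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise DataError("cohort spectrum must sum to 1")


@dataclass
class ContextComposition:
    """Counts of the 32 pyrimidine-collapsed trinucleotide contexts."""

    counts: np.ndarray
    total: int = field(init=False)
    skipped: int = 0  # interior positions with ambiguous bases

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (32,):
            raise DataError("context composition must have 32 entries")
        self.total = int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise EmptyInputError("context composition is empty")
        return self.counts / self.total


@dataclass
class LocalSpectrum:
    """A gene-local channel distribution (sums to 1; zero where the gene
    lacks the channel's source context)."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (96,):
            raise DataError("local spectrum must have 96 channels")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise DataError("local spectrum must sum to 1")


class SequenceContext:
    """Resolve trinucleotide contexts from named reference sequences.

    Positions are 1-based into the stored sequence; a context is resolvable
    for positions 2 .. len-1 (interior positions). For a focal gene supply
    the flanked coding sequence under the gene's name, with catalogue
    positions expressed in flanked-sequence coordinates.
    """

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "SequenceContext":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def triplet(self, chrom: str, pos: int) -> str:
        try:
            seq = self.sequences[chrom]
        except KeyError as exc:
            raise DataError(f"no reference sequence named {chrom!r}") from exc
        if pos < 2 or pos > len(seq) - 1:
            raise DataError(f"{chrom}:{pos} has no interior trinucleotide context")
        return seq[pos - 2 : pos + 1]


def sample_spectra(
    records: list[MutationRecord],
    context_source: SequenceContext | GeneModel,
    min_snvs: int = 50,
    missense_only: bool = False,
) -> tuple[list[SampleSpectrum], list[str]]:
    """Per-sample 96-channel spectra, keeping samples with >= ``min_snvs``.

    Returns ``(spectra, excluded_sample_ids)``. Only SNV records contribute;
    with ``missense_only`` the tally is further restricted to missense SNVs.
    A record whose reference allele disagrees with the sequence raises
    :class:`ReferenceMismatchError`.
    """
    if isinstance(context_source, GeneModel):
        context_source = SequenceContext(
            {context_source.gene: context_source.cds_with_flanks}
        )

    by_sample: dict[str, np.ndarray] = {}
    skipped_ambiguous = 0
    for rec in records:
        if not rec.is_snv:
            continue
        if missense_only and rec.variant_class.value != "missense":
            continue
        triplet = context_source.triplet(rec.chrom, rec.pos)
        if triplet[1] != rec.ref_allele:
            raise ReferenceMismatchError(
                f"{rec.sample_id} {rec.chrom}:{rec.pos} ref {rec.ref_allele} "
                f"disagrees with sequence base {triplet[1]}"
            )
        try:
            channel = classify_channel(rec.ref_allele, rec.alt_allele, triplet[0], triplet[2])
        except DataError:
            skipped_ambiguous += 1
            continue
        counts = by_sample.setdefault(rec.sample_id, np.zeros(96, dtype=np.int64))
        counts[channel.index] += 1
    if skipped_ambiguous:
        logger.warning("skipped %d SNVs with ambiguous context", skipped_ambiguous)

    spectra, excluded = [], []
    for sample_id in sorted(by_sample):
        spec = SampleSpectrum(sample_id, by_sample[sample_id])
        if spec.total_snvs >= min_snvs:
            spectra.append(spec)
        else:
            excluded.append(sample_id)
    return spectra, excluded


def mean_spectrum(spectra: list[SampleSpectrum], pooled: bool = False) -> CohortSpectrum:
    """Cohort spectrum: mean of per-sample proportions (default) or the
    normalized pooled channel counts (``pooled=True``)."""
    if not spectra:
        raise EmptyInputError("no sample spectra to average")
    if pooled:
        total = np.sum([s.counts for s in spectra], axis=0).astype(float)
        probs = total / total.sum()
    else:
        props = np.stack([s.proportions() for s in spectra])
        probs = props.mean(axis=0)
    probs = probs / probs.sum()  # guard rounding
    return CohortSpectrum(probs=probs, n_samples=len(spectra))


def context_composition(seq: str | GeneModel) -> ContextComposition:
    """Pyrimidine-collapsed trinucleotide composition of a flanked sequence.

    Every interior position contributes once; purine-centred triplets are
    counted under their reverse complement. Interior positions involving a
    non-ACGT base are tallied separately as skipped.
    """
    if isinstance(seq, GeneModel):
        seq = seq.cds_with_flanks
    seq = seq.upper()
    if len(seq) < 3:
        raise EmptyInputError("sequence shorter than one trinucleotide")
    counts = np.zeros(32, dtype=np.int64)
    skipped = 0
    for i in range(1, len(seq) - 1):
        triplet = seq[i - 1 : i + 2]
        if any(b not in BASES for b in triplet):
            skipped += 1
            continue
        if triplet[1] in "AG":
            triplet = revcomp(triplet)
        counts[_CONTEXT_INDEX[triplet]] += 1
    if skipped:
        logger.warning("context_composition: skipped %d ambiguous positions", skipped)
    comp = ContextComposition(counts=counts)
    comp.skipped = skipped
    return comp


def renormalize_to_gene(
    exome: CohortSpectrum,
    f_exome: ContextComposition,
    f_gene: ContextComposition,
) -> LocalSpectrum:
    """Carry the exome-wide spectrum to a gene's local context composition.

    Each channel is reweighted by the ratio of the gene's to the exome's
    frequency of its source trinucleotide, then the vector is renormalized
    to sum to 1. Channels whose context is absent from the gene get
    probability 0; an exome composition lacking a context that the spectrum
    and the gene both use is degenerate.
    """
    g_freq = f_gene.frequencies()
    e_freq = f_exome.frequencies()
    ctx = CHANNEL_CONTEXT_INDEX
    weights = np.zeros(96)
    for i in range(96):
        c = ctx[i]
        if g_freq[c] == 0.0:
            continue  # context absent from the gene -> probability 0
        if e_freq[c] == 0.0:
            if exome.probs[i] > 0:
                raise DegenerateModelError(
                    f"exome composition lacks context {CONTEXTS[c]} needed by "
                    f"channel {CHANNELS[i].label}"
                )
            continue
        weights[i] = exome.probs[i] * g_freq[c] / e_freq[c]
    total = weights.sum()
    if total == 0:
        raise DegenerateModelError("renormalized spectrum is identically zero")
    return LocalSpectrum(probs=weights / total)
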