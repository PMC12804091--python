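"""Generators for synthetic inputs with the structure the analyses assume.

Every generator is driven by a single integer seed through named
substreams, so each kind of output can be regenerated independently and
byte-identically. The defaults emulate a liver-cancer-like study: ~100
exomes with ~200 SNVs each drawn from a context-dependent substitution-rate
vector dominated by C>T (with an extra CpG boost) and T>C, a focal
100-codon gene that can carry a positional hotspot excess, a tumour cohort
in which activating mutations co-occur with copy gain of a second gene in
~80% of cases alongside a one-log2-unit expression shift, and 9-layer
lobule profiles built from four archetype shapes plus noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog_io import GeneModel, MutationRecord, VariantClass, write_mutation_catalog
from .cohort_genomics import DEFAULT_HOTSPOTS
from .errors import ConfigError
from .hotspot_model import CODON_TO_AA
from .spectrum import CHANNELS, classify_channel

__all__ = [
    "SimulationConfig",
    "default_true_rates",
    "simulate_sequences",
    "simulate_catalog",
    "simulate_gene_catalog",
    "simulate_cohort",
    "simulate_layer_profiles",
    "write_all",
]

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}

# named substreams so generators can be re-run independently
_STREAMS = {"sequences": 11, "catalog": 13, "cohort": 17, "layers": 19, "gene_catalog": 23}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


def default_true_rates() -> np.ndarray:
    """Per-channel relative substitution rates for a liver-like process.

    Emulates the concentration of real hepatocellular-carcinoma spectra:
    C>T and T>C transitions dominate, C>T at CpG (NCG contexts) is strongly
    elevated (clock-like deamination), A[T>C] carries the liver-specific
    transcription-damage peak, and G[C>A] is moderately boosted
    (aflatoxin-like). The vector is a relative rate per context site, not a
    probability.
    """
    class_weight = {"CA": 1.0, "CG": 0.3, "CT": 3.0, "TA": 0.5, "TC": 3.0, "TG": 0.3}
    rates = np.empty(96)
    for ch in CHANNELS:
        w = class_weight[ch.ref + ch.alt]
        if ch.ref == "C" and ch.alt == "T" and ch.flank3 == "G":
            w *= 8.0  # CpG deamination
        if ch.ref == "T" and ch.alt == "C" and ch.flank5 == "A":
            w *= 8.0  # A[T>C] liver peak
        if ch.ref == "C" and ch.alt == "A" and ch.flank5 == "G":
            w *= 3.0  # aflatoxin-like G[C>A]
        rates[ch.index] = w
    return rates


@dataclass
class SimulationConfig:
    seed: int = 0
    # mutation catalogue
    n_samples: int = 100
    snvs_per_sample: int = 200
    poisson_counts: bool = False
    true_rates: np.ndarray = field(default_factory=default_true_rates)
    exome_length: int = 10_000
    # focal gene
    focal_gene: str = "CTNNB1"
    focal_gene_length_codons: int = 100
    hotspot_codon: int | None = None
    hotspot_fold: float = 1.0
    # cohort
    cohort_n: int = 500
    p_activated: float = 0.3
    p_gain_given_activated: float = 0.8
    p_gain_background: float = 0.3
    expression_baseline_log2: float = 10.0
    expression_effect_log2: float = 1.0
    expression_noise_sd: float = 0.5
    # zonation
    genes_per_archetype: int = 25
    layer_noise_sd: float = 0.1

    def __post_init__(self):
        self.true_rates = np.asarray(self.true_rates, dtype=float)
        if self.true_rates.shape != (96,) or (self.true_rates < 0).any():
            raise ConfigError("true_rates must be 96 nonnegative reals")
        if not self.true_rates.any():
            raise ConfigError("true_rates are all zero")
        for p in (self.p_activated, self.p_gain_given_activated, self.p_gain_background):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.hotspot_fold < 1.0:
            raise ConfigError("hotspot_fold must be >= 1")
        if self.focal_gene_length_codons < 1 or self.exome_length < 3:
            raise ConfigError("sequence lengths too small")
        if self.hotspot_codon is not None and not (
            1 <= self.hotspot_codon <= self.focal_gene_length_codons
        ):
            raise ConfigError("hotspot_codon outside the gene")


def simulate_sequences(cfg: SimulationConfig) -> tuple[str, GeneModel]:
    """Uniform-base exome surrogate plus a stop-free focal gene with flanks.

    Gene codons are drawn uniformly; any draw that lands on a stop codon is
    redrawn, which keeps the reading frame valid for genes of any length.
    """
    rng = _rng(cfg.seed, "sequences")
    exome = "".join(rng.choice(list(BASES), size=cfg.exome_length))
    codons = []
    while len(codons) < cfg.focal_gene_length_codons:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in STOP_CODONS:
            codons.append(codon)
    flank5, flank3 = rng.choice(list(BASES)), rng.choice(list(BASES))
    gene = GeneModel(
        gene=cfg.focal_gene,
        strand="+",
        cds_with_flanks=flank5 + "".join(codons) + flank3,
    )
    return exome, gene


def _site_alt_outcomes(seq: str, rates: np.ndarray):
    """All (1-based interior position, alt) outcomes with their relative rates."""
    positions, alts, weights = [], [], []
    for pos in range(2, len(seq)):
        ref = seq[pos - 1]
        f5, f3 = seq[pos - 2], seq[pos]
        for alt in BASES:
            if alt == ref:
                continue
            ch = classify_channel(ref, alt, f5, f3)
            positions.append(pos)
            alts.append(alt)
            weights.append(rates[ch.index])
    return np.array(positions), np.array(alts), np.array(weights, dtype=float)


def _gene_record(
    gene: GeneModel, pos: int, alt: str, sample_id: str
) -> MutationRecord:
    """Record for an SNV at a 1-based flanked-sequence position of the gene."""
    cds_pos = pos - 1  # 1-based CDS coordinate
    residue = (cds_pos - 1) // 3 + 1
    site = (cds_pos - 1) % 3
    codon = gene.codon(residue)
    mutant = codon[:site] + alt + codon[site + 1 :]
    aa_ref, aa_alt = CODON_TO_AA[codon], CODON_TO_AA[mutant]
    if aa_alt == aa_ref:
        vclass = VariantClass.SYNONYMOUS
    elif aa_alt == "*":
        vclass = VariantClass.NONSENSE
    else:
        vclass = VariantClass.MISSENSE
    return MutationRecord(
        sample_id=sample_id,
        chrom=gene.gene,
        pos=pos,
        ref_allele=gene.cds_with_flanks[pos - 1],
        alt_allele=alt,
        variant_class=vclass,
        gene=gene.gene,
        protein_pos=residue,
    )


def _gene_outcomes(cfg: SimulationConfig, gene: GeneModel):
    positions, alts, weights = _site_alt_outcomes(gene.cds_with_flanks, cfg.true_rates)
    if cfg.hotspot_codon is not None and cfg.hotspot_fold > 1.0:
        residues = (positions - 2) // 3 + 1
        weights = np.where(residues == cfg.hotspot_codon, weights * cfg.hotspot_fold, weights)
    return positions, alts, weights


def simulate_catalog(
    cfg: SimulationConfig, exome: str, gene: GeneModel
) -> list[MutationRecord]:
    """Per-sample SNV catalogues over the exome surrogate and the focal gene.

    Each SNV is drawn (with replacement across samples, duplicates within a
    sample collapsed) with probability proportional to the channel rate of
    its (site, alt) outcome; sites in the hotspot codon are boosted by
    ``hotspot_fold``. Exome records carry variant class ``other``; gene
    records carry the consequence and residue computed by translation.
    Positions are 1-based in the named sequence (for the gene, in the
    flanked coding sequence).
    """
    rng = _rng(cfg.seed, "catalog")
    e_pos, e_alt, e_w = _site_alt_outcomes(exome, cfg.true_rates)
    g_pos, g_alt, g_w = _gene_outcomes(cfg, gene)
    n_e = len(e_pos)
    weights = np.concatenate([e_w, g_w])
    probs = weights / weights.sum()

    records: list[MutationRecord] = []
    for s in range(cfg.n_samples):
        sample_id = f"S{s + 1:04d}"
        n = (
            int(rng.poisson(cfg.snvs_per_sample))
            if cfg.poisson_counts
            else cfg.snvs_per_sample
        )
        draws = rng.choice(len(probs), size=n, replace=True, p=probs)
        for idx in sorted(set(int(d) for d in draws)):
            if idx < n_e:
                records.append(
                    MutationRecord(
                        sample_id=sample_id,
                        chrom="exome",
                        pos=int(e_pos[idx]),
                        ref_allele=exome[e_pos[idx] - 1],
                        alt_allele=str(e_alt[idx]),
                        variant_class=VariantClass.OTHER,
                        gene="",
                        protein_pos=None,
                    )
                )
            else:
                j = idx - n_e
                records.append(
                    _gene_record(gene, int(g_pos[j]), str(g_alt[j]), sample_id)
                )
    return records


def simulate_gene_catalog(
    cfg: SimulationConfig, gene: GeneModel, n_mutations: int, seed: int | None = None
) -> list[MutationRecord]:
    """Draw ``n_mutations`` SNVs restricted to the focal gene.

    Used to study positional excess at fixed mutation depth; all records
    share one pseudo-sample.
    """
    rng = np.random.default_rng(seed) if seed is not None else _rng(cfg.seed, "gene_catalog")
    g_pos, g_alt, g_w = _gene_outcomes(cfg, gene)
    probs = g_w / g_w.sum()
    draws = rng.choice(len(probs), size=n_mutations, replace=True, p=probs)
    return [
        _gene_record(gene, int(g_pos[i]), str(g_alt[i]), "POOL") for i in draws
    ]


def simulate_cohort(cfg: SimulationConfig):
    """Tumour cohort with configurable mutation/copy-gain co-occurrence.

    Activation is Bernoulli(p_activated), realized as a hotspot missense
    record; gain is Bernoulli(p_gain_given_activated) for activated and
    Bernoulli(p_gain_background) otherwise, realized as GISTIC +1 or +2;
    expression is baseline + effect * gain + Gaussian noise on the log2
    scale, back-transformed to RSEM.
    """
    from .catalog_io import CohortTable

    rng = _rng(cfg.seed, "cohort")
    hotspots = sorted(DEFAULT_HOTSPOTS)
    rows, mutations, truth = [], {}, []
    for s in range(cfg.cohort_n):
        sample_id = f"T{s + 1:04d}"
        activated = rng.random() < cfg.p_activated
        p_gain = cfg.p_gain_given_activated if activated else cfg.p_gain_background
        gain = rng.random() < p_gain
        gistic = int(rng.choice([1, 2], p=[0.7, 0.3])) if gain else int(rng.choice([0, -1], p=[0.9, 0.1]))
        log2_expr = (
            cfg.expression_baseline_log2
            + cfg.expression_effect_log2 * gain
            + rng.normal(0.0, cfg.expression_noise_sd)
        )
        rsem = max(0.0, 2.0**log2_expr - 1.0)
        muts = []
        if activated:
            residue = int(rng.choice(hotspots))
            muts.append(
                MutationRecord(
                    sample_id=sample_id,
                    chrom="CTNNB1",
                    pos=3 * residue,
                    ref_allele="C",
                    alt_allele="T",
                    variant_class=VariantClass.MISSENSE,
                    gene="CTNNB1",
                    protein_pos=residue,
                )
            )
        rows.append(
            {
                "sample_id": sample_id,
                "gistic_call": gistic,
                "expression_rsem": rsem,
                "excluded": False,
            }
        )
        mutations[sample_id] = muts
        truth.append({"sample_id": sample_id, "activated": bool(activated), "gain": bool(gain)})
    table = pd.DataFrame(rows)
    return CohortTable(table=table, mutations=mutations), pd.DataFrame(truth)


def _archetype_shapes() -> dict[str, np.ndarray]:
    layers = np.arange(9, dtype=float)
    return {
        "pericentral": np.linspace(1.0, 0.1, 9),
        "periportal": np.linspace(0.1, 1.0, 9),
        "mid_peak": np.exp(-0.5 * ((layers - 4.0) / 1.5) ** 2),
        "flat": np.full(9, 0.5),
    }


def simulate_layer_profiles(
    cfg: SimulationConfig, amplitude: float = 100.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x 9-layer profiles from four archetypes plus Gaussian noise.

    Noise sd is ``layer_noise_sd`` times the amplitude; values are clipped
    at zero to keep the matrix nonnegative. Returns the matrix and the
    ground-truth archetype label per gene.
    """
    rng = _rng(cfg.seed, "layers")
    shapes = _archetype_shapes()
    rows, labels, names = [], [], []
    for label, shape in shapes.items():
        for g in range(cfg.genes_per_archetype):
            profile = amplitude * shape + rng.normal(
                0.0, cfg.layer_noise_sd * amplitude, size=9
            )
            rows.append(np.clip(profile, 0.0, None))
            labels.append(label)
            names.append(f"{label.upper()}_{g + 1:03d}")
    matrix = pd.DataFrame(
        rows, index=names, columns=[f"L{i}" for i in range(1, 10)]
    )
    return matrix, pd.Series(labels, index=names, name="archetype")


def expected_channel_distribution(rates: np.ndarray, context_counts: np.ndarray) -> np.ndarray:
    """Channel distribution implied by per-site rates over a composition.

    The probability of observing channel i in a catalogue drawn from
    ``rates`` over sites with pyrimidine-collapsed context counts
    ``context_counts`` (length 32) is proportional to
    ``rates[i] * context_counts[c(i)]``.
    """
    from .spectrum import CHANNEL_CONTEXT_INDEX

    weights = np.asarray(rates, dtype=float) * np.asarray(context_counts, dtype=float)[
        CHANNEL_CONTEXT_INDEX
    ]
    return weights / weights.sum()


def true_local_spectrum(rates: np.ndarray, gene: GeneModel):
    """The gene-local channel distribution implied by the generative rates."""
    from .spectrum import LocalSpectrum, context_composition

    comp = context_composition(gene)
    return LocalSpectrum(probs=expected_channel_distribution(rates, comp.counts))


def write_all(cfg: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Emit FASTA, minimal-TSV catalogue, cohort TSV, layer TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exome, gene = simulate_sequences(cfg)
    records = simulate_catalog(cfg, exome, gene)
    cohort, cohort_truth = simulate_cohort(cfg)
    layers, layer_truth = simulate_layer_profiles(cfg)

    paths = {}

    def _write(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        paths[name] = str(path)

    _write(
        "exome.fasta",
        lambda p: p.write_text(">exome\n" + "\n".join(
            exome[i : i + 80] for i in range(0, len(exome), 80)
        ) + "\n"),
    )
    _write(
        "gene.fasta",
        lambda p: p.write_text(f">{gene.gene}\n{gene.cds_with_flanks}\n"),
    )
    _write("catalog.tsv", lambda p: write_mutation_catalog(records, p))
    _write(
        "cohort.tsv",
        lambda p: cohort.table.drop(columns=["log2_expression"]).to_csv(
            p, sep="\t", index=False
        ),
    )
    _write(
        "cohort_mutations.tsv",
        lambda p: write_mutation_catalog(
            [m for muts in cohort.mutations.values() for m in muts], p
        ),
    )
    _write("layers.tsv", lambda p: layers.to_csv(p, sep="\t", index_label="gene"))

    cfg_dict = asdict(cfg)
    cfg_dict["true_rates"] = list(map(float, cfg_dict["true_rates"]))
    truth = {
        "config": cfg_dict,
        "cohort": cohort_truth.to_dict(orient="records"),
        "layer_archetypes": layer_truth.to_dict(),
    }
    _write("truth.json", lambda p: p.write_text(json.dumps(truth, indent=1)))
    return paths
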