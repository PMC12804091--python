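"""End-to-end orchestration: spectrum -> renormalize -> expect -> report.

A :class:`RunConfig` resolves every input path and analysis constant (the
defaults are the study's stated values: >= 50 SNVs per sample for the
spectrum, the hotspot/indel activating rule, GISTIC >= 1 for gain). The
pipeline writes per-stage TSV outputs plus a manifest recording the
package version, a hash of the resolved configuration, seeds, per-stage
row counts and the SHA-256 of every output file, so a rerun with the same
config is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog_io import read_cohort_table, read_gene_model, read_mutation_catalog
from .cohort_genomics import ActivatingRule, cooccurrence_summary
from .errors import ConfigError, HotxpectError
from .hotspot_model import (
    build_codon_site_table,
    expected_missense_profile,
    hotspot_excess_report,
    normalize_to_observed,
    observed_position_counts,
)
from .spectrum import (
    CHANNELS,
    SequenceContext,
    context_composition,
    mean_spectrum,
    renormalize_to_gene,
    sample_spectra,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    catalog: str
    exome_fasta: str
    gene_fasta: str
    outdir: str
    gene: str = "CTNNB1"
    dialect: str = "minimal_tsv"
    min_snvs: int = 50
    missense_only: bool = False
    pooled: bool = False
    exclude_samples: list[str] = field(default_factory=list)
    gain_threshold: int = 1
    cohort: str | None = None
    cohort_catalog: str | None = None  # focal-gene records for co-occurrence
    n_perm: int = 1000
    seed: int = 0
    top_k: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages and return the manifest (also written to disk).

    Stages: ``spectrum`` (per-sample and cohort spectra), ``renormalize``
    (gene-local spectrum), ``expect`` (predicted vs observed per-residue
    profile), ``report`` (ranked excess table); plus ``cooccur`` when a
    cohort table is configured. Any stage failure aborts with the stage
    name attached.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg.resolved(),
        "config_hash": cfg.config_hash(),
        "stages": [],
        "outputs": {},
    }

    stage = "spectrum"
    try:
        records = read_mutation_catalog(cfg.catalog, dialect=cfg.dialect)
        records = [r for r in records if r.sample_id not in set(cfg.exclude_samples)]
        gene = read_gene_model(cfg.gene_fasta, cfg.gene)
        context = SequenceContext.from_fasta(cfg.exome_fasta)
        context.sequences[gene.gene] = gene.cds_with_flanks
        spectra, low = sample_spectra(
            records, context, min_snvs=cfg.min_snvs, missense_only=cfg.missense_only
        )
        cohort_spec = mean_spectrum(spectra, pooled=cfg.pooled)
        spec_df = pd.DataFrame(
            {"channel": [c.label for c in CHANNELS], "probability": cohort_spec.probs}
        )
        spec_path = outdir / "cohort_spectrum.tsv"
        spec_df.to_csv(spec_path, sep="\t", index=False)
        manifest["stages"].append(
            {
                "name": stage,
                "n_records": len(records),
                "n_samples_kept": len(spectra),
                "n_samples_below_min_snvs": len(low),
            }
        )

        stage = "renormalize"
        exome_seq = next(iter(SequenceContext.from_fasta(cfg.exome_fasta).sequences.values()))
        f_exome = context_composition(exome_seq)
        f_gene = context_composition(gene)
        local = renormalize_to_gene(cohort_spec, f_exome, f_gene)
        local_path = outdir / "local_spectrum.tsv"
        pd.DataFrame(
            {"channel": [c.label for c in CHANNELS], "probability": local.probs}
        ).to_csv(local_path, sep="\t", index=False)
        manifest["stages"].append({"name": stage, "n_channels_nonzero": int((local.probs > 0).sum())})

        stage = "expect"
        table = build_codon_site_table(gene)
        predicted = expected_missense_profile(local, table)
        observed = observed_position_counts(records, gene)
        pe = normalize_to_observed(predicted, observed)
        expect_path = outdir / "position_expectation.tsv"
        pd.DataFrame(
            {
                "position": np.arange(1, gene.protein_length + 1),
                "observed": pe.observed,
                "predicted": pe.predicted,
                "ratio": pe.ratio,
            }
        ).to_csv(expect_path, sep="\t", index=False)
        manifest["stages"].append(
            {"name": stage, "n_positions": gene.protein_length, "observed_total": int(pe.observed.sum())}
        )

        stage = "report"
        report = hotspot_excess_report(pe)
        report_path = outdir / "hotspot_report.tsv"
        report.to_csv(report_path, sep="\t", index=False)
        top = report.head(cfg.top_k)
        summary = {
            "gene": cfg.gene,
            "observed_total": int(pe.observed.sum()),
            "predicted_total": float(pe.predicted.sum()),
            "top_positions": [
                {"position": int(r.position), "observed": int(r.observed), "ratio": float(r.ratio)}
                for r in top.itertuples()
            ],
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
        manifest["stages"].append({"name": stage, "top_k": cfg.top_k})

        if cfg.cohort is not None:
            stage = "cooccur"
            cohort_records = (
                read_mutation_catalog(cfg.cohort_catalog, dialect=cfg.dialect)
                if cfg.cohort_catalog
                else records
            )
            cohort = read_cohort_table(cfg.cohort, cohort_records, gene=cfg.gene)
            summary_co = cooccurrence_summary(
                cohort, ActivatingRule(), gain_threshold=cfg.gain_threshold
            )
            co_path = outdir / "cooccurrence.json"
            co_path.write_text(
                json.dumps(
                    {
                        "n_total": summary_co.n_total,
                        "n_activated": summary_co.n_activated,
                        "n_activated_with_gain": summary_co.n_activated_with_gain,
                        "proportion_gain": summary_co.proportion_gain,
                    },
                    indent=1,
                )
            )
            manifest["stages"].append(
                {"name": stage, "n_activated": summary_co.n_activated}
            )
    except HotxpectError as exc:
        raise HotxpectError(f"stage {stage!r} failed: {exc}") from exc

    for path in sorted(outdir.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
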