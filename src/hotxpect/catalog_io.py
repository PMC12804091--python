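"""Mutation catalogues, gene models and cohort tables.

Conventions shared by the whole pipeline:

* genomic positions and protein residues are 1-based and inclusive (the MAF
  convention);
* a :class:`GeneModel` stores the *coding-strand* sequence with one flanking
  base on each side, so channel classification (which is strand-symmetric)
  never needs the genomic strand;
* expression values are analysed as ``log2(RSEM + 1)`` — the transform is
  applied at load time with a pseudo-count of 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    AlphabetError,
    EmptyInputError,
    FrameError,
    RecordError,
    SchemaError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "MutationRecord",
    "GeneModel",
    "CohortTable",
    "read_mutation_catalog",
    "write_mutation_catalog",
    "read_gene_model",
    "read_cohort_table",
    "filter_low_expression",
    "log2_rsem",
    "MAF_COLUMNS",
    "MINIMAL_COLUMNS",
]

VALID_BASES = frozenset("ACGT")


class VariantClass(str, Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"
    IN_FRAME_INDEL = "in_frame_indel"
    FRAMESHIFT = "frameshift"
    OTHER = "other"


#: MAF Variant_Classification -> internal enum. Unlisted classes map to OTHER.
MAF_CLASS_MAP = {
    "Missense_Mutation": VariantClass.MISSENSE,
    "Silent": VariantClass.SYNONYMOUS,
    "Nonsense_Mutation": VariantClass.NONSENSE,
    "In_Frame_Del": VariantClass.IN_FRAME_INDEL,
    "In_Frame_Ins": VariantClass.IN_FRAME_INDEL,
    "Frame_Shift_Del": VariantClass.FRAMESHIFT,
    "Frame_Shift_Ins": VariantClass.FRAMESHIFT,
}

MAF_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Hugo_Symbol",
    "Protein_position",
]

MINIMAL_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "gene",
    "protein_pos",
]


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call.

    ``protein_pos`` is ``None`` (unknown), an ``int`` (single residue) or an
    inclusive ``(start, end)`` residue range for indels.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass
    gene: str
    protein_pos: int | tuple[int, int] | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise RecordError(f"position {self.pos} < 1")
        if self.is_snv:
            if self.ref_allele == self.alt_allele:
                raise RecordError(
                    f"SNV with ref == alt ({self.ref_allele}) at {self.chrom}:{self.pos}"
                )
        if isinstance(self.protein_pos, tuple):
            start, end = self.protein_pos
            if start > end:
                raise RecordError(f"protein range {start}-{end} has start > end")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in VALID_BASES
            and self.alt_allele in VALID_BASES
        )

    @property
    def protein_start(self) -> int | None:
        if self.protein_pos is None:
            return None
        if isinstance(self.protein_pos, tuple):
            return self.protein_pos[0]
        return self.protein_pos

    @property
    def protein_range(self) -> tuple[int, int] | None:
        if self.protein_pos is None:
            return None
        if isinstance(self.protein_pos, tuple):
            return self.protein_pos
        return (self.protein_pos, self.protein_pos)


@dataclass(frozen=True)
class GeneModel:
    """Coding-strand CDS of length 3L with one flanking base on each side.

    ``cds_with_flanks`` therefore has length ``3L + 2``; index ``p`` (1-based
    into the flanked sequence, i.e. CDS position ``p``) is
    ``cds_with_flanks[p]`` in 0-based Python indexing.
    """

    gene: str
    strand: str
    cds_with_flanks: str
    protein_length: int = field(init=False)

    def __post_init__(self):
        seq = self.cds_with_flanks.upper()
        object.__setattr__(self, "cds_with_flanks", seq)
        if self.strand not in {"+", "-"}:
            raise RecordError(f"strand must be + or -, got {self.strand!r}")
        if len(seq) < 5 or (len(seq) - 2) % 3 != 0:
            raise FrameError(
                f"{self.gene}: flanked CDS length {len(seq)} is not 3L + 2"
            )
        bad = set(seq) - VALID_BASES
        if bad:
            raise AlphabetError(f"{self.gene}: non-ACGT characters {sorted(bad)}")
        object.__setattr__(self, "protein_length", (len(seq) - 2) // 3)
        protein = str(Seq(self.cds).translate())
        if "*" in protein[:-1]:
            raise FrameError(f"{self.gene}: internal stop codon in translation")

    @property
    def cds(self) -> str:
        return self.cds_with_flanks[1:-1]

    def codon(self, residue: int) -> str:
        """Codon (3 nt) for a 1-based protein residue."""
        i = 1 + 3 * (residue - 1)
        return self.cds_with_flanks[i : i + 3]

    def triplet(self, cds_pos: int) -> str:
        """Trinucleotide context centred on a 1-based CDS position."""
        return self.cds_with_flanks[cds_pos - 1 : cds_pos + 2]


@dataclass
class CohortTable:
    """Per-tumour gene-level calls for the co-occurrence analysis.

    ``table`` has one row per sample with columns ``sample_id``,
    ``gistic_call``, ``expression_rsem``, ``log2_expression`` and
    ``excluded``; ``mutations`` maps sample_id to its focal-gene records.
    """

    table: pd.DataFrame
    mutations: dict[str, list[MutationRecord]]

    def __post_init__(self):
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise SchemaError(f"duplicated sample_id(s): {sorted(set(dup))}")
        if (self.table["expression_rsem"] < 0).any():
            raise RecordError("negative expression_rsem value")
        if "log2_expression" not in self.table.columns:
            self.table = self.table.assign(
                log2_expression=log2_rsem(self.table["expression_rsem"])
            )

    def active_samples(self) -> pd.DataFrame:
        """Rows not flagged as excluded (e.g. mismatch-repair deficient)."""
        return self.table[~self.table["excluded"]]


def log2_rsem(values):
    """log2(RSEM + 1) with the conventional pseudo-count of 1."""
    import numpy as np

    return np.log2(np.asarray(values, dtype=float) + 1.0)


def _parse_protein_pos(raw: str | float | None, line: int):
    if raw is None:
        return None
    text = str(raw).strip()
    if text in {"", ".", "nan", "NA", "None", "-"}:
        return None
    # cBioPortal MAFs write "41/781" (position / protein length)
    text = text.split("/")[0]
    if "-" in text:
        try:
            start_s, end_s = text.split("-")
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise RecordError(f"unparsable protein position {raw!r}", line) from exc
        return (start, end)
    try:
        return int(text)
    except ValueError as exc:
        raise RecordError(f"unparsable protein position {raw!r}", line) from exc


def _check_header(fields: list[str], required: list[str]):
    seen = set()
    for name in fields:
        if name in seen:
            raise SchemaError(f"duplicated header column {name!r}")
        seen.add(name)
    for name in required:
        if name not in seen:
            raise SchemaError(f"missing required column {name!r}")


def read_mutation_catalog(
    path: str | Path, dialect: str = "minimal_tsv"
) -> list[MutationRecord]:
    """Read a tab-separated mutation catalogue.

    Parameters
    ----------
    path
        TSV file; lines starting with ``#`` are comments.
    dialect
        ``"maf"`` (cBioPortal/TCGA column names, Variant_Classification
        vocabulary) or ``"minimal_tsv"`` (the 8 canonical columns
        ``sample_id chrom pos ref alt variant_class gene protein_pos``).
    """
    path = Path(path)
    if dialect not in {"maf", "minimal_tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    required = MAF_COLUMNS if dialect == "maf" else MINIMAL_COLUMNS

    records: list[MutationRecord] = []
    header: dict[str, int] | None = None
    with path.open() as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                _check_header(fields, required)
                header = {name: i for i, name in enumerate(fields)}
                continue
            records.append(_parse_row(fields, header, dialect, lineno))
    if header is None:
        raise SchemaError(f"{path}: no header line found")
    return records


def _parse_row(
    fields: list[str], header: dict[str, int], dialect: str, lineno: int
) -> MutationRecord:
    def get(col: str) -> str:
        idx = header[col]
        if idx >= len(fields):
            raise RecordError(f"row has too few columns for {col!r}", lineno)
        return fields[idx]

    if dialect == "maf":
        raw_class = get("Variant_Classification")
        vclass = MAF_CLASS_MAP.get(raw_class, VariantClass.OTHER)
        sample = get("Tumor_Sample_Barcode")
        chrom = get("Chromosome")
        pos_raw = get("Start_Position")
        ref, alt = get("Reference_Allele"), get("Tumor_Seq_Allele2")
        gene = get("Hugo_Symbol")
        ppos_raw = get("Protein_position")
    else:
        raw_class = get("variant_class")
        try:
            vclass = VariantClass(raw_class)
        except ValueError as exc:
            raise RecordError(f"unknown variant_class {raw_class!r}", lineno) from exc
        sample = get("sample_id")
        chrom = get("chrom")
        pos_raw = get("pos")
        ref, alt = get("ref"), get("alt")
        gene = get("gene")
        ppos_raw = get("protein_pos")

    try:
        pos = int(pos_raw)
    except ValueError as exc:
        raise RecordError(f"unparsable position {pos_raw!r}", lineno) from exc

    record = MutationRecord(
        sample_id=sample,
        chrom=chrom,
        pos=pos,
        ref_allele=ref.upper(),
        alt_allele=alt.upper(),
        variant_class=vclass,
        gene=gene,
        protein_pos=_parse_protein_pos(ppos_raw, lineno),
    )
    if record.variant_class is VariantClass.IN_FRAME_INDEL and record.protein_pos is None:
        # unusable by the activating classifier but not fatal
        logger.warning("line %d: in-frame indel without protein position", lineno)
    return record


def write_mutation_catalog(records: list[MutationRecord], path: str | Path) -> None:
    """Write records in the minimal TSV dialect (lossless round-trip)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(MINIMAL_COLUMNS) + "\n")
        for rec in records:
            if rec.protein_pos is None:
                ppos = "."
            elif isinstance(rec.protein_pos, tuple):
                ppos = f"{rec.protein_pos[0]}-{rec.protein_pos[1]}"
            else:
                ppos = str(rec.protein_pos)
            fh.write(
                "\t".join(
                    [
                        rec.sample_id,
                        rec.chrom,
                        str(rec.pos),
                        rec.ref_allele,
                        rec.alt_allele,
                        rec.variant_class.value,
                        rec.gene,
                        ppos,
                    ]
                )
                + "\n"
            )


def read_gene_model(fasta_path: str | Path, gene: str, strand: str = "+") -> GeneModel:
    """Load a flanked coding sequence for ``gene`` from a FASTA file.

    The record id must equal the gene symbol and the sequence must be the
    coding-strand CDS with exactly one extra base on each end (length
    ``3L + 2``). Lower-case input is upper-cased.
    """
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id == gene:
            return GeneModel(gene=gene, strand=strand, cds_with_flanks=str(rec.seq))
    raise SchemaError(f"no FASTA record named {gene!r} in {fasta_path}")


def read_cohort_table(
    cohort_path: str | Path,
    mutation_records: list[MutationRecord] | None = None,
    gene: str = "CTNNB1",
) -> CohortTable:
    """Read a cohort TSV (sample_id, gistic_call, expression_rsem, excluded).

    Focal-gene mutation records, if supplied, are attached per sample.
    """
    df = pd.read_csv(cohort_path, sep="\t", comment="#")
    _check_header(list(df.columns), ["sample_id", "gistic_call", "expression_rsem"])
    if "excluded" not in df.columns:
        df["excluded"] = False
    df["excluded"] = df["excluded"].astype(bool)
    df["gistic_call"] = df["gistic_call"].astype(int)
    muts: dict[str, list[MutationRecord]] = {s: [] for s in df["sample_id"]}
    for rec in mutation_records or []:
        if rec.gene == gene and rec.sample_id in muts:
            muts[rec.sample_id].append(rec)
    return CohortTable(table=df, mutations=muts)


def filter_low_expression(
    expr_matrix: pd.DataFrame, threshold: float = 5.0
) -> pd.Index:
    """Genes whose mean log2(RSEM + 1) is at least ``threshold``.

    The input matrix is genes x samples, already on the log2(RSEM + 1)
    scale; genes with row mean strictly below the threshold are removed.
    """
    import numpy as np

    if expr_matrix.shape[0] == 0 or expr_matrix.shape[1] == 0:
        raise EmptyInputError("expression matrix is empty")
    values = expr_matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise RecordError("expression matrix contains non-finite values")
    means = values.mean(axis=1)
    return expr_matrix.index[means >= threshold]
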