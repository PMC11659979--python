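"""Plain-text readers and writers for the formats the pipeline touches.

Supported formats: MAF (Mutation Annotation Format) somatic-variant tables,
two-column sample/gene mutation tables, tab-separated PPI edge lists (with an
optional source-count column), GMT gene-set files (Broad dialect), and the
pathway x sample score matrix written as TSV.

All files are UTF-8 text; both LF and CRLF line endings are accepted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "MutationProfile",
    "PathwayCollection",
    "DEFAULT_NONSILENT_CLASSES",
    "read_maf",
    "read_mutation_table",
    "write_mutation_table",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_score_matrix",
    "write_score_matrix",
]


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


#: Conventional set of MAF Variant_Classification values treated as nonsilent
#: (protein-affecting). Configurable via the ``nonsilent_classes`` argument of
#: :func:`read_maf`.
DEFAULT_NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)

_REQUIRED_MAF_COLUMNS = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")


@dataclass(frozen=True)
class MutationProfile:
    """Per-sample set of nonsilently mutated gene symbols.

    Set semantics: a gene mutated twice in the same sample counts once.
    """

    sample_id: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be a non-empty string")
        if any(not g for g in self.genes):
            raise ValueError("gene symbols must be non-empty strings")


@dataclass
class PathwayCollection:
    """Named gene sets (e.g. KEGG pathways) with optional descriptions."""

    pathways: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[str]:
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id]

    def items(self):
        return self.pathways.items()


def read_maf(
    path,
    nonsilent_classes: Iterable[str] = DEFAULT_NONSILENT_CLASSES,
) -> list[MutationProfile]:
    """Read a MAF file into one :class:`MutationProfile` per sample.

    Only rows whose ``Variant_Classification`` is in ``nonsilent_classes``
    contribute genes; a sample present only through silent rows yields an
    empty profile. Profiles are returned sorted by sample id, so the result
    is invariant to row order. Lines starting with ``#`` (MAF version
    pragmas) are ignored.
    """
    nonsilent = frozenset(nonsilent_classes)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file has no MAF header line") from None
    for col in _REQUIRED_MAF_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required MAF column {col!r}")
    genes_by_sample: dict[str, set[str]] = {}
    n_dropped = 0
    for sample, gene, vclass in zip(
        df["Tumor_Sample_Barcode"], df["Hugo_Symbol"], df["Variant_Classification"]
    ):
        sample = sample.strip()
        if not sample:
            continue
        bucket = genes_by_sample.setdefault(sample, set())
        gene = gene.strip()
        if vclass.strip() not in nonsilent:
            n_dropped += 1
            continue
        if gene:
            bucket.add(gene)
    if n_dropped:
        logger.info("read_maf: dropped %d silent/unlisted variant rows", n_dropped)
    return [
        MutationProfile(sample_id=s, genes=frozenset(g))
        for s, g in sorted(genes_by_sample.items())
    ]


def read_mutation_table(path) -> list[MutationProfile]:
    """Read a two-column TSV (sample_id, gene_symbol; optional header).

    Same contract as :func:`read_maf` but without classification filtering;
    duplicate (sample, gene) rows are deduplicated.
    """
    genes_by_sample: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            sample, gene = fields[0].strip(), fields[1].strip()
            if lineno == 1 and sample.lower() in {"sample", "sample_id", "tumor_sample_barcode"}:
                continue
            if not sample or not gene:
                raise FormatError(f"{path}:{lineno}: empty sample id or gene symbol")
            genes_by_sample.setdefault(sample, set()).add(gene)
    return [
        MutationProfile(sample_id=s, genes=frozenset(g))
        for s, g in sorted(genes_by_sample.items())
    ]


def write_mutation_table(cohort: Iterable[MutationProfile], path) -> None:
    """Write a cohort as a two-column TSV with a header line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgene_symbol\n")
        for profile in cohort:
            for gene in sorted(profile.genes):
                fh.write(f"{profile.sample_id}\t{gene}\n")


def read_edge_list(path, min_sources: int | None = None) -> list[tuple[str, str]]:
    """Read an undirected edge list TSV (gene_a, gene_b[, source_count]).

    Self-loops are dropped and duplicate pairs (either orientation) collapsed.
    When ``min_sources`` is given, the third column is required and only edges
    supported by strictly more than ``min_sources`` sources are retained.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 2 tab-separated fields"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise FormatError(f"{path}:{lineno}: empty gene symbol")
            if min_sources is not None:
                if len(fields) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: min_sources given but no source-count column"
                    )
                try:
                    count = int(fields[2].strip())
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: source count {fields[2]!r} is not an integer"
                    ) from None
                if count <= min_sources:
                    continue
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(key)
    return pairs


def write_edge_list(pairs: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_gmt(path) -> PathwayCollection:
    """Read a GMT gene-set file: name, description, then member genes per line."""
    pathways: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields "
                    f"(name, description, genes...)"
                )
            pid = fields[0].strip()
            if pid in pathways:
                raise FormatError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {pid!r} has no genes")
            pathways[pid] = genes
            descriptions[pid] = fields[1].strip()
    return PathwayCollection(pathways=pathways, descriptions=descriptions)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, genes in collection.items():
            desc = collection.descriptions.get(pid, "")
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


def write_score_matrix(scores, path) -> None:
    """Write a pathway x sample score matrix as TSV at full float precision.

    ``scores`` may be a :class:`~ssmutpa.enrichment.ScoreMatrix` or a pandas
    DataFrame (rows = pathways, columns = samples). Values round-trip
    bit-for-bit through :func:`read_score_matrix`.
    """
    frame = getattr(scores, "frame", scores)
    if frame.empty:
        logger.warning("write_score_matrix: writing an empty score matrix to %s", path)
    frame.to_csv(path, sep="\t", index_label="pathway")


def read_score_matrix(path) -> pd.DataFrame:
    """Read a score matrix TSV written by :func:`write_score_matrix`."""
    return pd.read_csv(path, sep="\t", index_col="pathway", float_precision="round_trip")
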