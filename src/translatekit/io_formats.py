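"""Readers/writers for the external formats the pipeline touches.

The shared tabular model is :class:`ExpressionMatrix` (genes x samples with
per-sample metadata and per-gene biotype).  All genomic intervals are held
internally as 0-based half-open coordinates; GTF input/output converts at the
boundary (GTF is 1-based, fully closed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "GeneRecord",
    "ExpressionMatrix",
    "TranscriptModel",
    "ENSEMBL_BIOTYPES",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_rmats_jc",
    "write_rmats_jc",
]

FRACTIONS = ("total", "polysomal")

#: Ensembl biotypes seen in practice; used as the default allow-list.
#: Unknown biotypes warn rather than fail, since annotation releases differ.
ENSEMBL_BIOTYPES = frozenset(
    {
        "protein_coding",
        "lincRNA",
        "lncRNA",
        "processed_transcript",
        "antisense",
        "pseudogene",
        "processed_pseudogene",
        "unprocessed_pseudogene",
        "miRNA",
        "snoRNA",
        "snRNA",
        "rRNA",
        "misc_RNA",
        "TEC",
        "sense_intronic",
        "sense_overlapping",
        "3prime_overlapping_ncrna",
    }
)


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: condition x RNA fraction x replicate."""

    sample_id: str
    condition: str
    fraction: str  # "total" (transcriptome) or "polysomal" (translatome)
    replicate: int

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValueError(
                f"fraction must be one of {FRACTIONS}, got {self.fraction!r}"
            )
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


@dataclass(frozen=True)
class GeneRecord:
    """Gene identity plus its Ensembl biotype."""

    gene_id: str
    gene_name: str | None = None
    biotype: str = "protein_coding"
    length: int | None = None

    def __post_init__(self) -> None:
        if not self.biotype:
            raise ValueError(f"gene {self.gene_id}: biotype must be non-empty")
        if self.length is not None and self.length <= 0:
            raise ValueError(f"gene {self.gene_id}: length must be positive")
        if self.biotype not in ENSEMBL_BIOTYPES:
            warnings.warn(
                f"gene {self.gene_id}: biotype {self.biotype!r} is not in the "
                "Ensembl allow-list",
                stacklevel=2,
            )


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript.

    ``exons`` are (start, end) genome intervals in 0-based half-open
    coordinates, ordered 5'->3' in transcript orientation (i.e. reverse
    genomic order on the minus strand).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if e <= s:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon ({s}, {e}) is empty"
                )
        genomic = sorted(exons)
        for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


class ExpressionMatrix:
    """Genes x samples expression values with metadata.

    ``unit`` is ``"raw_counts"`` or ``"CPM"``; values must be non-negative and
    dimensions must agree with the gene and sample lists.
    """

    def __init__(
        self,
        genes: Sequence[GeneRecord],
        samples: Sequence[SampleMeta],
        values: np.ndarray,
        unit: str = "raw_counts",
    ) -> None:
        if unit not in ("raw_counts", "CPM"):
            raise ValueError(f"unknown unit {unit!r}")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(genes), len(samples)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        if np.any(values < 0):
            raise ValueError("expression values must be non-negative")
        if np.any(~np.isfinite(values)):
            raise ValueError("expression values must be finite")
        ids = [g.gene_id for g in genes]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate gene id {dup!r}")
        sids = [s.sample_id for s in samples]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate sample ids")
        self.genes = list(genes)
        self.samples = list(samples)
        self.values = values
        self.unit = unit
        self._gene_index = {g: i for i, g in enumerate(ids)}

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self._gene_index[gene_id]]

    def sample_indices(
        self, condition: str | None = None, fraction: str | None = None
    ) -> list[int]:
        out = []
        for i, s in enumerate(self.samples):
            if condition is not None and s.condition != condition:
                continue
            if fraction is not None and s.fraction != fraction:
                continue
            out.append(i)
        return out

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.genes,
            [self.samples[i] for i in indices],
            self.values[:, list(indices)],
            unit=self.unit,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.samples == other.samples
            and self.unit == other.unit
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return (
            f"ExpressionMatrix({len(self.genes)} genes x "
            f"{len(self.samples)} samples, unit={self.unit})"
        )


# -- counts TSV ---------------------------------------------------------------


def read_counts_tsv(
    path: str | Path,
    metadata: Mapping[str, SampleMeta],
    biotypes: Mapping[str, str] | None = None,
    gene_id_column: str = "gene_id",
) -> ExpressionMatrix:
    """Read a featureCounts-style gene x sample count table.

    ``metadata`` maps the file's sample column names to :class:`SampleMeta`.
    Every numeric column must be mapped; missing cells are an error, not zero.
    ``biotypes`` optionally assigns per-gene biotypes (else protein_coding).
    """
    df = pd.read_csv(path, sep="\t")
    if gene_id_column not in df.columns:
        raise ValueError(f"missing gene id column {gene_id_column!r}")
    sample_cols = [c for c in df.columns if c != gene_id_column]
    unmapped = [c for c in sample_cols if c not in metadata]
    if unmapped:
        raise ValueError(f"sample columns without metadata: {unmapped}")
    ids = df[gene_id_column].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id {dup.iloc[0]!r}")
    values = df[sample_cols].to_numpy()
    if values.dtype == object or pd.isna(values.astype(float)).any():
        raise ValueError("non-numeric or missing count cell")
    values = values.astype(float)
    if (values < 0).any():
        raise ValueError("negative count")
    genes = [
        GeneRecord(g, biotype=(biotypes or {}).get(g, "protein_coding"))
        for g in ids
    ]
    samples = [metadata[c] for c in sample_cols]
    return ExpressionMatrix(genes, samples, values, unit="raw_counts")


def write_counts_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV (integer cells when counts are integral)."""
    df = matrix.to_frame()
    if matrix.unit == "raw_counts" and np.allclose(
        matrix.values, np.round(matrix.values)
    ):
        df = df.astype(np.int64)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# -- GTF ----------------------------------------------------------------------


def read_gtf(path: str | Path) -> tuple[list[GeneRecord], list[TranscriptModel]]:
    """Parse an Ensembl-dialect GTF into gene records and transcript models.

    GTF coordinates (1-based, inclusive) are converted to 0-based half-open;
    exon lists are ordered 5'->3' in transcript orientation.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneRecord] = []
    for g in db.features_of_type("gene"):
        biotype = g.attributes.get("gene_biotype", ["protein_coding"])[0]
        name = g.attributes.get("gene_name", [None])[0]
        genes.append(
            GeneRecord(
                gene_id=g.id,
                gene_name=name,
                biotype=biotype,
                length=g.end - g.start + 1,
            )
        )
    transcripts: list[TranscriptModel] = []
    for t in db.features_of_type("transcript"):
        exons = []
        for ex in db.children(t, featuretype="exon"):
            exons.append((ex.start - 1, ex.end))  # to 0-based half-open
        if not exons:
            raise ValueError(f"transcript {t.id} has no exons")
        exons.sort(reverse=(t.strand == "-"))
        gene_id = t.attributes.get("gene_id", [t.id])[0]
        transcripts.append(
            TranscriptModel(
                transcript_id=t.id,
                gene_id=gene_id,
                chrom=t.seqid,
                strand=t.strand,
                exons=tuple(exons),
            )
        )
    orphans = set()
    tids = {t.transcript_id for t in transcripts}
    for ex in db.features_of_type("exon"):
        parent = ex.attributes.get("transcript_id", [None])[0]
        if parent not in tids:
            orphans.add(parent)
    if orphans:
        raise ValueError(f"exons without parent transcript: {sorted(map(str, orphans))}")
    return genes, transcripts


def write_gtf(
    genes: Sequence[GeneRecord],
    transcripts: Sequence[TranscriptModel],
    path: str | Path,
    source: str = "translatekit",
) -> None:
    """Write gene/transcript/exon features as Ensembl-dialect GTF."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    with open(path, "w") as fh:
        for gene in genes:
            ts = by_gene.get(gene.gene_id, [])
            if not ts:
                continue
            gstart = min(min(s for s, _ in t.exons) for t in ts)
            gend = max(max(e for _, e in t.exons) for t in ts)
            strand = ts[0].strand
            chrom = ts[0].chrom
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            )
            if gene.gene_name:
                attrs += f' gene_name "{gene.gene_name}";'
            fh.write(
                f"{chrom}\t{source}\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\t{attrs}\n"
            )
            for t in ts:
                tstart = min(s for s, _ in t.exons)
                tend = max(e for _, e in t.exons)
                tattrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_biotype "{gene.biotype}";'
                )
                fh.write(
                    f"{t.chrom}\t{source}\ttranscript\t{tstart + 1}\t{tend}\t.\t"
                    f"{t.strand}\t.\t{tattrs}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                        f"{t.strand}\t.\t{tattrs}\n"
                    )


# -- FASTA --------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase DNA sequence}."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{rec.id}: non-DNA characters {sorted(bad)}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- rMATS JC tables ----------------------------------------------------------

RMATS_COORD_COLUMNS: dict[str, tuple[str, ...]] = {
    "SE": (
        "exonStart_0base",
        "exonEnd",
        "upstreamES",
        "upstreamEE",
        "downstreamES",
        "downstreamEE",
    ),
    "MXE": (
        "1stExonStart_0base",
        "1stExonEnd",
        "2ndExonStart_0base",
        "2ndExonEnd",
        "upstreamES",
        "upstreamEE",
        "downstreamES",
        "downstreamEE",
    ),
    "A3SS": (
        "longExonStart_0base",
        "longExonEnd",
        "shortES",
        "shortEE",
        "flankingES",
        "flankingEE",
    ),
    "A5SS": (
        "longExonStart_0base",
        "longExonEnd",
        "shortES",
        "shortEE",
        "flankingES",
        "flankingEE",
    ),
    "RI": (
        "riExonStart_0base",
        "riExonEnd",
        "upstreamES",
        "upstreamEE",
        "downstreamES",
        "downstreamEE",
    ),
}


def _mean_inclusion(cell: object) -> float:
    """rMATS stores per-replicate inclusion levels comma-separated; NA allowed."""
    parts = [p for p in str(cell).split(",") if p not in ("NA", "nan", "")]
    if not parts:
        return float("nan")
    return float(np.mean([float(p) for p in parts]))


def read_rmats_jc(
    paths_by_type: Mapping[str, str | Path],
    comparison: str = "",
    biotypes: Mapping[str, str] | None = None,
):
    """Read rMATS junction-count output tables, one per event type.

    ``paths_by_type`` maps an event type in {SE, MXE, A3SS, A5SS, RI} to its
    TSV.  Inclusion-level difference (deltaPSI) and p-values are carried
    through unchanged.  Returns a list of
    :class:`translatekit.splicing_events.SplicingEvent`.
    """
    from .splicing_events import SplicingEvent

    events: list[SplicingEvent] = []
    for event_type, path in paths_by_type.items():
        if event_type not in RMATS_COORD_COLUMNS:
            raise ValueError(f"unknown event type {event_type!r}")
        df = pd.read_csv(path, sep="\t")
        required = ("GeneID", "PValue", "IncLevel1", "IncLevel2", "IncLevelDifference")
        coord_cols = RMATS_COORD_COLUMNS[event_type]
        missing = [c for c in required + coord_cols if c not in df.columns]
        if missing:
            raise ValueError(f"{event_type} table missing columns: {missing}")
        for _, row in df.iterrows():
            p = float(row["PValue"])
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value {p} outside [0, 1]")
            inc1 = _mean_inclusion(row["IncLevel1"])
            inc2 = _mean_inclusion(row["IncLevel2"])
            for inc in (inc1, inc2):
                if np.isfinite(inc) and not 0.0 <= inc <= 1.0:
                    raise ValueError(f"inclusion level {inc} outside [0, 1]")
            dpsi = float(row["IncLevelDifference"])
            if not -1.0 <= dpsi <= 1.0:
                raise ValueError(f"inclusion-level difference {dpsi} outside [-1, 1]")
            gene_id = str(row["GeneID"]).strip('"')
            coords = tuple(int(row[c]) for c in coord_cols)
            events.append(
                SplicingEvent(
                    event_id=f"{event_type}:{gene_id}:{row.get('ID', len(events))}",
                    event_type=event_type,
                    gene_id=gene_id,
                    biotype=(biotypes or {}).get(gene_id, "protein_coding"),
                    comparison=comparison,
                    delta_psi=dpsi,
                    p=p,
                    coordinates=coords,
                )
            )
    return events


def write_rmats_jc(events, directory: str | Path) -> dict[str, Path]:
    """Write events back out as one rMATS-style JC TSV per event type."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_type: dict[str, list] = {}
    for ev in events:
        by_type.setdefault(ev.event_type, []).append(ev)
    paths: dict[str, Path] = {}
    for event_type, evs in by_type.items():
        coord_cols = RMATS_COORD_COLUMNS[event_type]
        rows = []
        for i, ev in enumerate(evs):
            row = {"ID": i, "GeneID": ev.gene_id, "geneSymbol": ev.gene_id,
                   "chr": "chr1", "strand": "+"}
            coords = ev.coordinates or tuple(range(len(coord_cols)))
            row.update(dict(zip(coord_cols, coords)))
            inc1 = min(1.0, max(0.0, 0.5 + ev.delta_psi / 2))
            inc2 = min(1.0, max(0.0, 0.5 - ev.delta_psi / 2))
            row.update(
                {
                    "PValue": ev.p,
                    "FDR": ev.p,
                    "IncLevel1": f"{inc1:.6f},{inc1:.6f}",
                    "IncLevel2": f"{inc2:.6f},{inc2:.6f}",
                    "IncLevelDifference": ev.delta_psi,
                }
            )
            rows.append(row)
        path = directory / f"{event_type}.MATS.JC.txt"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        paths[event_type] = path
    return paths
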