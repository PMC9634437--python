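"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the study design: two conditions (enzalutamide-
sensitive "CRPC", resistant "ER") x two RNA fractions (total transcriptome,
heavy-polysomal translatome) x replicates, with negative-binomial gene
counts over a mix of biotypes.  A planted global translation-efficiency
down-shift affects a fraction of mRNAs and a TE up-shift a fraction of
lncRNAs, in the resistant condition only; the translatome mean of a gene is
its transcriptome mean times 2^(true log2 TE ratio) there, and times 1 in
the sensitive condition.  Ground truth is returned alongside every dataset
so recovery can be scored.

Also generated: a three-group proteome table coupled to the planted TE
shifts with lognormal noise, rMATS-style splicing-event tables with planted
direction categories, and spliced transcripts carrying ORFs with exact
requested Kozak contexts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneRecord, SampleMeta, TranscriptModel
from .splicing_events import EVENT_TYPES, SplicingEvent
from .io_formats import RMATS_COORD_COLUMNS

__all__ = [
    "SimConfig",
    "ORFSpec",
    "simulate_counts",
    "simulate_proteome",
    "simulate_splicing_events",
    "simulate_transcripts",
]

SENSITIVE = "CRPC"
RESISTANT = "ER"
LNC_BIOTYPES = ("lincRNA", "processed_transcript")


@dataclass
class SimConfig:
    """Study-condition parameters for the count simulation.

    Defaults mirror the emulated design: 2000 genes dominated by
    protein_coding with lincRNA/processed_transcript minorities, 3 replicates
    per condition x fraction, shared negative-binomial dispersion 0.1
    (variance mu + phi*mu^2), a -0.4 log2 TE shift planted in 20% of mRNAs
    and a +0.5 shift in 15% of lncRNAs (resistant condition only), and
    lognormal proteome noise of sd 0.2 (natural-log scale).
    """

    n_genes: int = 2000
    biotype_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "protein_coding": 0.80,
            "lincRNA": 0.12,
            "processed_transcript": 0.08,
        }
    )
    n_reps: int = 3
    baseline_log_mean: float = 4.0  # natural-log scale of NB mean counts
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    frac_mrna_te_down: float = 0.20
    mrna_te_shift_log2: float = -0.4
    frac_lnc_te_up: float = 0.15
    lnc_te_shift_log2: float = 0.5
    proteome_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_reps <= 0:
            raise ValueError("n_reps must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        total = sum(self.biotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"biotype proportions sum to {total}, not 1")
        for name in ("frac_mrna_te_down", "frac_lnc_te_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _largest_remainder_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Integer category sizes matching proportions exactly in total."""
    raw = {k: n * p for k, p in proportions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    leftover = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:leftover]:
        counts[k] += 1
    return counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion*mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean).astype(float)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def simulate_counts(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Simulate paired transcriptome/translatome count matrices plus truth.

    Per-gene baseline means are lognormal; library sizes vary uniformly
    within 2-fold of nominal so CPM normalization is exercised; counts are
    negative binomial with the shared dispersion.  Returns (transcriptome,
    translatome, truth table) where the truth table has one row per gene:
    gene_id, biotype, true_log2_te_ratio, is_te_shifted, base_mean.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    sizes = _largest_remainder_counts(n, config.biotype_proportions)
    biotypes: list[str] = []
    for bt, k in sizes.items():
        biotypes.extend([bt] * k)
    gene_ids = [f"G{i:05d}" for i in range(n)]
    genes = [GeneRecord(g, biotype=bt) for g, bt in zip(gene_ids, biotypes)]

    base_mean = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)

    shift = np.zeros(n)
    is_mrna = np.array([bt == "protein_coding" for bt in biotypes])
    is_lnc = np.array([bt in LNC_BIOTYPES for bt in biotypes])
    mrna_idx = np.where(is_mrna)[0]
    lnc_idx = np.where(is_lnc)[0]
    n_mrna_shift = int(round(config.frac_mrna_te_down * len(mrna_idx)))
    n_lnc_shift = int(round(config.frac_lnc_te_up * len(lnc_idx)))
    mrna_shifted = rng.choice(mrna_idx, size=n_mrna_shift, replace=False)
    lnc_shifted = rng.choice(lnc_idx, size=n_lnc_shift, replace=False)
    shift[mrna_shifted] = config.mrna_te_shift_log2
    shift[lnc_shifted] = config.lnc_te_shift_log2

    def make_matrix(fraction: str) -> ExpressionMatrix:
        samples: list[SampleMeta] = []
        cols: list[np.ndarray] = []
        for condition in (SENSITIVE, RESISTANT):
            for rep in range(1, config.n_reps + 1):
                lib_factor = rng.uniform(0.5, 2.0)
                mean = base_mean * lib_factor
                if fraction == "polysomal" and condition == RESISTANT:
                    mean = mean * np.exp2(shift)
                cols.append(_nb_draw(rng, mean, config.nb_dispersion))
                samples.append(
                    SampleMeta(
                        sample_id=f"{condition}_{fraction}_{rep}",
                        condition=condition,
                        fraction=fraction,
                        replicate=rep,
                    )
                )
        return ExpressionMatrix(
            genes, samples, np.column_stack(cols), unit="raw_counts"
        )

    transcriptome = make_matrix("total")
    translatome = make_matrix("polysomal")
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "biotype": biotypes,
            "true_log2_te_ratio": shift,
            "is_te_shifted": shift != 0,
            "base_mean": base_mean,
        }
    )
    return transcriptome, translatome, truth


def simulate_proteome(
    truth: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Protein abundances for 3 groups x 3 replicates, coupled to TE truth.

    Abundance is proportional to the transcriptome baseline in VCaP and
    CRPC, and to baseline x 2^(true log2 TE ratio) in the resistant ER
    group, with multiplicative lognormal noise of sd ``proteome_noise_sd``.
    Returns (table indexed by gene_id, column->group mapping).
    """
    rng = np.random.default_rng(config.seed + 1)
    base = truth["base_mean"].to_numpy()
    shift = truth["true_log2_te_ratio"].to_numpy()
    groups = {}
    data = {}
    for group in ("VCaP", "CRPC", "ER"):
        expected = base * (np.exp2(shift) if group == "ER" else 1.0)
        for rep in range(1, 4):
            col = f"{group}_{rep}"
            noise = (
                rng.lognormal(0.0, config.proteome_noise_sd, size=len(base))
                if config.proteome_noise_sd > 0
                else 1.0
            )
            data[col] = expected * noise
            groups[col] = group
    table = pd.DataFrame(data, index=pd.Index(truth["gene_id"], name="protein_id"))
    return table, groups


def simulate_splicing_events(
    n_events: int,
    class_mix: Mapping[str, float],
    seed: int = 0,
    biotype_proportions: Mapping[str, float] | None = None,
    event_type_proportions: Mapping[str, float] | None = None,
) -> tuple[list[SplicingEvent], list[SplicingEvent], pd.DataFrame]:
    """Plant splicing events with known direction categories.

    ``class_mix`` gives target proportions over the four categories
    (CRPC_only, ER_only, shared_same, shared_opposite).  Returns the two
    per-comparison event lists (already significant-by-construction events
    plus, for the "_only" categories, a non-significant counterpart in the
    other comparison) and the truth table.  Significant events draw
    p ~ U(0, 0.05) and |deltaPSI| ~ U(0.15, 0.6); non-significant
    counterparts draw p ~ U(0.3, 1).
    """
    rng = np.random.default_rng(seed)
    mix_total = sum(class_mix.values())
    if abs(mix_total - 1.0) > 1e-9:
        raise ValueError(f"class_mix proportions sum to {mix_total}, not 1")
    unknown = set(class_mix) - {"CRPC_only", "ER_only", "shared_same", "shared_opposite"}
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    sizes = _largest_remainder_counts(n_events, class_mix)
    bt_props = biotype_proportions or {"protein_coding": 0.7, "lincRNA": 0.3}
    et_props = event_type_proportions or {t: 1 / len(EVENT_TYPES) for t in EVENT_TYPES}

    events_crpc: list[SplicingEvent] = []
    events_er: list[SplicingEvent] = []
    rows = []
    i = 0
    for category, size in sizes.items():
        for _ in range(size):
            event_type = rng.choice(list(et_props), p=list(et_props.values()))
            biotype = rng.choice(list(bt_props), p=list(bt_props.values()))
            gene_id = f"SG{i:05d}"
            anchor = int(rng.integers(1_000, 1_000_000))
            n_coords = len(RMATS_COORD_COLUMNS[event_type])
            coords = tuple(anchor + 100 * k for k in range(n_coords))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            dpsi = sign * rng.uniform(0.15, 0.6)
            p_sig = rng.uniform(0.0, 0.0499)

            def make(comparison: str, significant: bool, flip: bool = False):
                return SplicingEvent(
                    event_id=f"{event_type}:{gene_id}:{comparison}",
                    event_type=event_type,
                    gene_id=gene_id,
                    biotype=biotype,
                    comparison=comparison,
                    delta_psi=(-dpsi if flip else dpsi)
                    if significant
                    else sign * rng.uniform(0.0, 0.09),
                    p=p_sig if significant else rng.uniform(0.3, 1.0),
                    coordinates=coords,
                )

            if category == "CRPC_only":
                events_crpc.append(make("CRPC_trans_vs_poly", True))
                events_er.append(make("ER_trans_vs_poly", False))
            elif category == "ER_only":
                events_crpc.append(make("CRPC_trans_vs_poly", False))
                events_er.append(make("ER_trans_vs_poly", True))
            elif category == "shared_same":
                events_crpc.append(make("CRPC_trans_vs_poly", True))
                events_er.append(make("ER_trans_vs_poly", True))
            else:  # shared_opposite
                events_crpc.append(make("CRPC_trans_vs_poly", True))
                events_er.append(make("ER_trans_vs_poly", True, flip=True))
            rows.append(
                {
                    "gene_id": gene_id,
                    "event_type": event_type,
                    "biotype": biotype,
                    "true_category": category,
                }
            )
            i += 1
    return events_crpc, events_er, pd.DataFrame(rows)


# -- transcript / ORF simulation ----------------------------------------------


@dataclass(frozen=True)
class ORFSpec:
    """Requested ORF for a simulated transcript.

    ``kozak_context`` is the 10-base -6..+4 window (DNA or RNA alphabet)
    whose positions 7-9 must be ATG; ``peptide_length`` counts amino acids
    (excluding the stop).
    """

    kozak_context: str = "GAGAAGATGG"
    peptide_length: int = 20
    utr5_length: int = 30
    utr3_length: int = 30

    def __post_init__(self) -> None:
        ctx = self.kozak_context.upper().replace("U", "T")
        if len(ctx) != 10 or ctx[6:9] != "ATG":
            raise ValueError(
                f"kozak context {self.kozak_context!r} must be 10 bases with "
                "ATG at positions 7-9"
            )
        object.__setattr__(self, "kozak_context", ctx)
        if self.peptide_length < 1:
            raise ValueError("peptide_length must be >= 1")
        if self.utr5_length < 6:
            raise ValueError("utr5_length must be >= 6 to hold the -6..-1 context")


#: codons free of A and T cannot create ATG or stop codons anywhere,
#: including across codon junctions
_SAFE_CODONS = ("GGC", "GCC", "CGC", "CCG", "GCG", "GGG", "CCC", "CGG")


def _repair_stray_atg(seq: str, planted_start: int, protected: tuple[int, int]) -> str:
    """Remove any ATG other than the planted one by mutating its G to C.

    Raises if a stray ATG lies inside the protected window (the planted
    context plus ORF), which can only happen when the requested context
    itself embeds an additional ATG.
    """
    chars = list(seq)
    idx = seq.find("ATG")
    while idx != -1:
        if idx != planted_start:
            if not protected[0] <= idx + 2 < protected[1]:
                chars[idx + 2] = "C"  # drop the G, outside the context/ORF
            elif not protected[0] <= idx < protected[1]:
                chars[idx] = "C"  # junction ATG: drop its A in the UTR instead
            else:
                raise ValueError(
                    "requested Kozak context embeds an ATG besides positions 7-9"
                )
        idx = "".join(chars).find("ATG", idx + 1)
    return "".join(chars)


def _random_atg_free(rng: np.random.Generator, length: int) -> str:
    """Random DNA with no ATG substring (occurrences are repaired)."""
    seq = list(rng.choice(list("ACGT"), size=length))
    s = "".join(seq)
    while "ATG" in s:
        pos = s.index("ATG")
        seq[pos + 2] = "C"
        s = "".join(seq)
    return s


def simulate_transcripts(
    n: int,
    orf_spec: ORFSpec | Sequence[ORFSpec | None] | None = None,
    seed: int = 0,
    n_exons_range: tuple[int, int] = (1, 3),
) -> tuple[dict[str, str], list[GeneRecord], list[TranscriptModel], pd.DataFrame]:
    """Simulate a genome, spliced transcript models, and planted ORFs.

    ``orf_spec`` is one spec applied to every transcript, a per-transcript
    sequence (None entries give ORF-free, ATG-free transcripts), or None for
    all ORF-free.  Each planted ORF begins with ATG, ends with a stop codon,
    carries exactly the requested -6..+4 context after splicing, and is the
    only ATG on its transcript, so ORF recovery is exact.  Transcripts are
    laid on one chromosome with random intron gaps; strands alternate.

    Returns (genome {chrom: sequence}, gene records, transcript models,
    planted-ORF table with transcript_id/start/end/kozak_context/peptide).
    """
    from .orf_kozak import translate

    rng = np.random.default_rng(seed)
    if orf_spec is None or isinstance(orf_spec, ORFSpec):
        specs: list[ORFSpec | None] = [orf_spec] * n
    else:
        specs = list(orf_spec)
        if len(specs) != n:
            raise ValueError("orf_spec sequence length must equal n")

    chrom = "chrS"
    genome_parts: list[str] = []
    cursor = 0
    genes: list[GeneRecord] = []
    transcripts: list[TranscriptModel] = []
    planted_rows = []

    for t_i, spec in enumerate(specs):
        tid = f"T{t_i:04d}"
        gid = f"TG{t_i:04d}"
        if spec is None:
            spliced = _random_atg_free(rng, int(rng.integers(120, 300)))
            biotype = "lincRNA"
        else:
            utr5 = _random_atg_free(rng, spec.utr5_length)
            utr5 = utr5[: spec.utr5_length - 6] + spec.kozak_context[:6]
            # codon 2 starts with the +4 context base and completes with two
            # A/T-free bases; remaining codons come whole from the safe set,
            # so the coding body cannot contain ATG or stop codons
            body = [spec.kozak_context[9] + rng.choice(("GC", "CC", "GG", "CG"))]
            for _ in range(spec.peptide_length - 2):
                body.append(rng.choice(_SAFE_CODONS))
            stop = rng.choice(("TAA", "TAG"))
            utr3 = _random_atg_free(rng, spec.utr3_length)
            cds = "ATG" + "".join(body) + stop
            start = spec.utr5_length
            end = start + 3 * (spec.peptide_length + 1)
            spliced = _repair_stray_atg(
                utr5 + cds + utr3, start, protected=(start - 6, end)
            )
            biotype = "lincRNA"
            planted_rows.append(
                {
                    "transcript_id": tid,
                    "start": start,
                    "end": end,
                    "kozak_context": spec.kozak_context.replace("T", "U"),
                    "peptide": translate(spliced[start:end]),
                }
            )

        # split the spliced sequence into exons and place on the genome
        n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        n_exons = min(n_exons, len(spliced) // 20) or 1
        cuts = sorted(
            rng.choice(np.arange(10, len(spliced) - 10), size=n_exons - 1, replace=False)
        ) if n_exons > 1 else []
        pieces = [
            spliced[a:b]
            for a, b in zip([0] + list(cuts), list(cuts) + [len(spliced)])
        ]
        strand = "+" if t_i % 2 == 0 else "-"
        genomic_pieces = pieces if strand == "+" else [
            _revcomp(p) for p in reversed(pieces)
        ]
        intervals: list[tuple[int, int]] = []
        for k, piece in enumerate(genomic_pieces):
            gap = int(rng.integers(20, 80))
            genome_parts.append(_random_atg_free(rng, gap))
            cursor += gap
            genome_parts.append(piece)
            intervals.append((cursor, cursor + len(piece)))
            cursor += len(piece)
        exons = tuple(intervals) if strand == "+" else tuple(reversed(intervals))
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=exons,
            )
        )
        genes.append(GeneRecord(gid, biotype=biotype))

    tail = _random_atg_free(rng, 50)
    genome = {chrom: "".join(genome_parts) + tail}
    return genome, genes, transcripts, pd.DataFrame(planted_rows)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
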