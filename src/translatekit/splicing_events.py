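"""Cross-classification of alternative-splicing events between transcriptome
and translatome.

Events (rMATS-style, with per-event inclusion-level difference deltaPSI and
p-value) are filtered at p < 0.05 and |deltaPSI| > 0.1, then classified by
where they reach significance: in the enzalutamide-sensitive comparison only,
in the resistant comparison only, or in both (same or opposite deltaPSI sign).
Event types collapse to three classes: alternative exon choice (AEC = exon
skipping + mutually exclusive exons), alternative splice-site choice
(ASS = alternative 3' + 5' sites) and intron retention (IR).

Sign convention: deltaPSI = inclusion level in the transcriptome minus
inclusion level in the translatome.  This convention is recorded in all
output headers; "same/opposite direction" refers to the sign of deltaPSI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SplicingEvent",
    "EventClassification",
    "IsoformGroupQuant",
    "COLLAPSED_TYPES",
    "filter_events",
    "classify_direction",
    "event_type_composition",
    "compare_isoform_groups",
]

EVENT_TYPES = ("SE", "MXE", "A3SS", "A5SS", "RI")

#: SE and MXE collapse to alternative exon choice; A3SS/A5SS to alternative
#: splice site; RI stays intron retention.
COLLAPSED_TYPES: dict[str, str] = {
    "SE": "AEC",
    "MXE": "AEC",
    "A3SS": "ASS",
    "A5SS": "ASS",
    "RI": "IR",
}

CATEGORIES = ("CRPC_only", "ER_only", "shared_same", "shared_opposite")


@dataclass(frozen=True)
class SplicingEvent:
    """One rMATS-style event from a transcriptome-vs-translatome comparison.

    ``delta_psi`` is transcriptome minus translatome inclusion level.
    ``coordinates`` is the full event coordinate tuple; together with the
    event type and gene it defines event identity across comparisons (a 1-bp
    coordinate difference is a distinct event).
    """

    event_id: str
    event_type: str
    gene_id: str
    biotype: str
    comparison: str
    delta_psi: float
    p: float
    coordinates: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not -1.0 <= self.delta_psi <= 1.0:
            raise ValueError(f"delta_psi {self.delta_psi} outside [-1, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p {self.p} outside [0, 1]")

    @property
    def identity(self) -> tuple:
        return (self.event_type, self.gene_id, self.coordinates)

    @property
    def collapsed_type(self) -> str:
        return COLLAPSED_TYPES[self.event_type]


@dataclass(frozen=True)
class EventClassification:
    """Direction category and collapsed type for one classified event."""

    event_id: str
    event_type: str
    gene_id: str
    biotype: str
    collapsed_type: str
    category: str
    delta_psi_crpc: float  # nan when not significant in that comparison
    delta_psi_er: float


@dataclass(frozen=True)
class IsoformGroupQuant:
    """Per-sample counts for a group of isoforms sharing a splicing feature
    (e.g. all transcripts whose spliced form keeps the peptide-coding exon)."""

    label: str
    counts_by_sample: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts_by_sample.values()):
            raise ValueError("isoform counts must be non-negative")


def filter_events(
    events: Iterable[SplicingEvent],
    p_threshold: float = 0.05,
    dpsi_threshold: float = 0.1,
) -> list[SplicingEvent]:
    """Keep events with p < p_threshold AND |deltaPSI| > dpsi_threshold.

    Both inequalities are strict: an event at exactly p = 0.05 or
    |deltaPSI| = 0.1 is dropped.
    """
    return [
        ev
        for ev in events
        if ev.p < p_threshold and abs(ev.delta_psi) > dpsi_threshold
    ]


def classify_direction(
    events_crpc: Sequence[SplicingEvent],
    events_er: Sequence[SplicingEvent],
) -> list[EventClassification]:
    """Classify filtered events by which comparison(s) they are significant in.

    ``events_crpc`` and ``events_er`` are the *filtered* (significant) event
    sets of the sensitive (CRPC) and resistant (ER) comparisons, keyed by the
    shared event identity (type, gene, coordinates).  Categories:

    - ``CRPC_only`` / ``ER_only``: significant in one comparison only;
    - ``shared_same``: significant in both with equal deltaPSI sign;
    - ``shared_opposite``: significant in both with opposite signs.

    A deltaPSI of exactly 0 in both (impossible post-filter) would count as
    shared_same by convention.
    """

    def _index(events: Sequence[SplicingEvent], label: str):
        idx: dict[tuple, SplicingEvent] = {}
        for ev in events:
            if ev.identity in idx:
                raise ValueError(
                    f"duplicate event identity in {label} set: {ev.identity}"
                )
            idx[ev.identity] = ev
        return idx

    crpc = _index(events_crpc, "CRPC")
    er = _index(events_er, "ER")
    out: list[EventClassification] = []
    for key in list(crpc) + [k for k in er if k not in crpc]:
        ev_c = crpc.get(key)
        ev_e = er.get(key)
        ref = ev_c or ev_e
        assert ref is not None
        if ev_c is not None and ev_e is not None:
            same = np.sign(ev_c.delta_psi) == np.sign(ev_e.delta_psi)
            category = "shared_same" if same else "shared_opposite"
        elif ev_c is not None:
            category = "CRPC_only"
        else:
            category = "ER_only"
        out.append(
            EventClassification(
                event_id=ref.event_id,
                event_type=ref.event_type,
                gene_id=ref.gene_id,
                biotype=ref.biotype,
                collapsed_type=ref.collapsed_type,
                category=category,
                delta_psi_crpc=ev_c.delta_psi if ev_c else float("nan"),
                delta_psi_er=ev_e.delta_psi if ev_e else float("nan"),
            )
        )
    return out


def event_type_composition(
    classified: Sequence[EventClassification],
    by_biotype: bool = True,
    mrna_biotypes: frozenset[str] = frozenset({"protein_coding"}),
):
    """Tabulate collapsed event classes (AEC/ASS/IR) per cell line x biotype.

    Events significant in a given cell line (its ``_only`` category plus both
    shared categories) contribute to that line's column.  Returns a mapping
    from biotype stratum ("mRNA"/"lncRNA", or "all") to an enrichment result
    from :func:`translatekit.contingency_enrichment.biotype_enrichment`-style
    testing of the AEC/ASS/IR composition between the two lines.
    """
    from .contingency_enrichment import ContingencyTable, chi_squared_test

    def stratum(ev: EventClassification) -> str:
        if not by_biotype:
            return "all"
        return "mRNA" if ev.biotype in mrna_biotypes else "lncRNA"

    strata = sorted({stratum(ev) for ev in classified})
    results = {}
    for st in strata:
        evs = [ev for ev in classified if stratum(ev) == st]
        counts = {
            line: {ct: 0 for ct in ("AEC", "ASS", "IR")}
            for line in ("CRPC", "ER")
        }
        for ev in evs:
            in_crpc = ev.category in ("CRPC_only", "shared_same", "shared_opposite")
            in_er = ev.category in ("ER_only", "shared_same", "shared_opposite")
            if in_crpc:
                counts["CRPC"][ev.collapsed_type] += 1
            if in_er:
                counts["ER"][ev.collapsed_type] += 1
        table = ContingencyTable(
            row_labels=["AEC", "ASS", "IR"],
            col_labels=["CRPC", "ER"],
            observed=np.array(
                [[counts[line][ct] for line in ("CRPC", "ER")]
                 for ct in ("AEC", "ASS", "IR")],
                dtype=float,
            ),
        )
        results[st] = (table, chi_squared_test(table))
    return results


def compare_isoform_groups(
    group_a_counts: Sequence[float], group_b_counts: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sided t-test between two isoform-group count vectors.

    Returns (difference of means, p).  Used e.g. to compare abundance of
    peptide-exon-retaining JPX isoforms between cell lines.
    """
    a = np.asarray(group_a_counts, dtype=float)
    b = np.asarray(group_b_counts, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 values per group for a t-test")
    diff = float(a.mean() - b.mean())
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        return diff, 1.0  # identical constant groups: no evidence of difference
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return diff, float(p)
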