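"""Polymorphic-site detection and the exon/intron mutation spectrum.

A polymorphic site is an alignment column (or a merged run of gap columns)
showing at least two distinct states.  Each site carries one or more
mutation *events* classified as transition (A<->G, C<->T), transversion
(A<->C, A<->T, C<->G, G<->T) or indel (any gap involvement).  The spectrum
table aggregates event counts per class and per region (exon/intron) and
derives totals and percentages, mirroring the summary tables conventionally
reported for intron-rich amplicon loci.

Counting conventions
--------------------
* Columns containing ``N`` in any sequence are excluded entirely.
* A maximal run of consecutive gap-bearing columns whose gap pattern
  (which sequences are gapped) is identical is merged into ONE indel event
  whose length is the run length; column-wise counting would inflate indel
  counts for multi-base indels.
* Multi-allelic sites contribute ``(number of distinct non-gap states - 1)``
  events under the default ``"minimum"`` convention: each minor state is
  paired with the majority state (ties broken alphabetically) and each pair
  classified independently.  ``"all_pairs"`` counts every unordered pair.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .seqio import MultipleAlignment, RegionMap

__all__ = [
    "TRANSITION_PAIRS",
    "MUTATION_CLASSES",
    "MutationEvent",
    "PolymorphicSite",
    "SpectrumTable",
    "classify_mutation",
    "find_polymorphic_sites",
    "spectrum_table",
    "polymorphism_frequency",
    "haplotype_matrix",
    "group_haplotypes",
    "round_half_away",
    "truncate_percent",
]

TRANSITION_PAIRS = (frozenset("AG"), frozenset("CT"))

#: Row order of the spectrum table: the four substitution pair classes that
#: are transitions/transversions, plus indels.
MUTATION_CLASSES = ("A-G", "C-T", "A-C", "A-T", "C-G", "G-T", "indel")

TRANSITION_CLASSES = ("A-G", "C-T")
TRANSVERSION_CLASSES = ("A-C", "A-T", "C-G", "G-T")


def classify_mutation(state_a: str, state_b: str) -> str:
    """Classify a state pair as transition, transversion or indel.

    States are single bases or gap runs (strings of ``-``); the result is
    symmetric in its arguments.  Identical states raise ``ValueError``.
    """
    a, b = state_a.upper(), state_b.upper()
    if a == b:
        raise ValueError(f"states are identical: {a!r}")
    if "-" in a or "-" in b:
        return "indel"
    if len(a) != 1 or len(b) != 1 or a not in "ACGT" or b not in "ACGT":
        raise ValueError(f"states must be single bases or gaps: {a!r}, {b!r}")
    return "transition" if frozenset((a, b)) in TRANSITION_PAIRS else "transversion"


def _pair_class(state_a: str, state_b: str) -> str:
    """Spectrum-table class name for a state pair (e.g. ``"C-T"``)."""
    if "-" in state_a or "-" in state_b:
        return "indel"
    lo, hi = sorted((state_a, state_b))
    return f"{lo}-{hi}"


@dataclass(frozen=True)
class MutationEvent:
    state_a: str
    state_b: str
    kind: str  # transition | transversion | indel

    @property
    def class_name(self) -> str:
        return _pair_class(self.state_a, self.state_b)


@dataclass(frozen=True)
class PolymorphicSite:
    """One variable column (or merged indel run) of the alignment.

    ``position`` is the 1-based column of the site (first column for a
    merged run); ``span`` is 1 for substitutions and the run length for
    merged indels.
    """

    position: int
    region_label: str
    alleles: tuple[tuple[str, int], ...]  # (state, multiplicity), sorted
    events: tuple[MutationEvent, ...]
    span: int = 1

    @property
    def has_indel(self) -> bool:
        return any(e.kind == "indel" for e in self.events)


def _substitution_events(states: list[str], convention: str) -> list[MutationEvent]:
    """Events among the distinct non-gap states of one column."""
    distinct = sorted(set(states))
    if len(distinct) < 2:
        return []
    if convention == "all_pairs":
        pairs = [
            (distinct[i], distinct[j])
            for i in range(len(distinct))
            for j in range(i + 1, len(distinct))
        ]
    elif convention == "minimum":
        counts = Counter(states)
        # majority state; ties broken alphabetically
        majority = min(distinct, key=lambda s: (-counts[s], s))
        pairs = [(s, majority) for s in distinct if s != majority]
    else:
        raise ValueError(f"unknown multiallelic convention {convention!r}")
    return [MutationEvent(a, b, classify_mutation(a, b)) for a, b in pairs]


def find_polymorphic_sites(
    aln: MultipleAlignment,
    regions: RegionMap,
    multiallelic: str = "minimum",
) -> list[PolymorphicSite]:
    """Scan the alignment for polymorphic sites, sorted by position.

    Substitution variation is assessed per column over non-gap states;
    gap runs with a shared gap pattern are merged into single indel events
    (see module docstring).  Columns containing ``N`` are skipped.
    """
    if regions.length != aln.length:
        raise ValueError(
            f"region map covers {regions.length} columns, alignment has {aln.length}"
        )
    ncols = aln.length
    columns = [aln.column(p) for p in range(1, ncols + 1)]
    usable = [("N" not in col) for col in columns]

    sites: dict[int, PolymorphicSite] = {}

    # substitution events, column-wise
    for pos in range(1, ncols + 1):
        if not usable[pos - 1]:
            continue
        col = columns[pos - 1]
        nongap = [c for c in col if c != "-"]
        events = _substitution_events(nongap, multiallelic)
        if events:
            alleles = tuple(sorted(Counter(col).items()))
            sites[pos] = PolymorphicSite(
                position=pos,
                region_label=regions.label_at(pos),
                alleles=alleles,
                events=tuple(events),
            )

    # indel events: merge maximal runs of gap columns with identical pattern
    run_start = None
    run_pattern: tuple[int, ...] | None = None
    for pos in range(1, ncols + 2):  # sentinel column to flush the last run
        if pos <= ncols and usable[pos - 1]:
            col = columns[pos - 1]
            pattern = tuple(i for i, c in enumerate(col) if c == "-")
        else:
            pattern = ()
        if pattern and len(pattern) < len(aln):
            if run_pattern == pattern and run_start is not None:
                continue  # run extends
            if run_start is not None:
                _flush_indel_run(sites, aln, regions, columns, run_start, pos - 1)
            run_start, run_pattern = pos, pattern
        else:
            if run_start is not None:
                _flush_indel_run(sites, aln, regions, columns, run_start, pos - 1)
            run_start, run_pattern = None, None

    return [sites[p] for p in sorted(sites)]


def _flush_indel_run(
    sites: dict[int, PolymorphicSite],
    aln: MultipleAlignment,
    regions: RegionMap,
    columns: list[str],
    start: int,
    end: int,
) -> None:
    """Record one merged indel event for columns ``start..end`` (1-based)."""
    span = end - start + 1
    gapped = {i for i, c in enumerate(columns[start - 1]) if c == "-"}
    # the "present" allele across the run, from the first non-gapped sequence
    present_rows = [i for i in range(len(aln)) if i not in gapped]
    present = "".join(columns[p - 1][present_rows[0]] for p in range(start, end + 1))
    event = MutationEvent(present, "-" * span, "indel")
    col = columns[start - 1]
    alleles = tuple(sorted(Counter(col).items()))
    if start in sites:
        old = sites[start]
        sites[start] = PolymorphicSite(
            position=start,
            region_label=old.region_label,
            alleles=old.alleles,
            events=old.events + (event,),
            span=span,
        )
    else:
        sites[start] = PolymorphicSite(
            position=start,
            region_label=regions.label_at(start),
            alleles=alleles,
            events=(event,),
            span=span,
        )


# ---------------------------------------------------------------------------
# spectrum table


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed count tables)."""
    import math

    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def truncate_percent(x: float, ndigits: int = 1) -> float:
    """Truncate toward zero at ``ndigits`` decimals (per-nt frequency style)."""
    import math

    factor = 10**ndigits
    return math.trunc(x * factor) / factor


@dataclass(frozen=True)
class SpectrumTable:
    """Event counts per mutation class and region, with derived summaries.

    Percentages are always recomputed from the counts; nothing derived is
    stored.
    """

    counts: dict[str, dict[str, int]]  # class -> region -> count
    region_lengths: dict[str, int]

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.region_lengths)

    def count(self, klass: str, region: str | None = None) -> int:
        row = self.counts[klass]
        if region is None:
            return sum(row.values())
        return row.get(region, 0)

    def transitions(self, region: str | None = None) -> int:
        return sum(self.count(c, region) for c in TRANSITION_CLASSES)

    def transversions(self, region: str | None = None) -> int:
        return sum(self.count(c, region) for c in TRANSVERSION_CLASSES)

    def indels(self, region: str | None = None) -> int:
        return self.count("indel", region)

    def total(self, region: str | None = None) -> int:
        return sum(self.count(c, region) for c in MUTATION_CLASSES)

    def percent(self, numerator: int, region: str | None = None) -> float:
        """Share of the region's total mutations, in percent (exact)."""
        tot = self.total(region)
        return 100.0 * numerator / tot if tot else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Spectrum table as a DataFrame with integer-percent annotations."""
        regions = list(self.regions) + ["total"]

        def cell(count: int, region_total: int, with_pct: bool) -> str:
            if not with_pct or region_total == 0:
                return str(count)
            pct = int(round_half_away(100.0 * count / region_total))
            return f"{count} ({pct}%)"

        rows: dict[str, list[str]] = {}
        totals = {r: self.total(None if r == "total" else r) for r in regions}
        for klass in MUTATION_CLASSES:
            with_pct = klass in ("A-G", "C-T", "indel")
            rows[klass if klass != "indel" else "Indels"] = [
                cell(
                    self.count(klass, None if r == "total" else r),
                    totals[r],
                    with_pct,
                )
                for r in regions
            ]
        rows["Total transitions"] = [
            cell(self.transitions(None if r == "total" else r), totals[r], True)
            for r in regions
        ]
        rows["Total transversions"] = [
            cell(self.transversions(None if r == "total" else r), totals[r], True)
            for r in regions
        ]
        rows["Total mutations"] = [str(totals[r]) for r in regions]
        rows["Length (nt)"] = [
            str(
                sum(self.region_lengths.values())
                if r == "total"
                else self.region_lengths[r]
            )
            for r in regions
        ]
        order = [
            "A-G",
            "C-T",
            "Total transitions",
            "A-C",
            "A-T",
            "C-G",
            "G-T",
            "Total transversions",
            "Indels",
            "Total mutations",
            "Length (nt)",
        ]
        frame = pd.DataFrame(rows, index=regions).T
        return frame.loc[order]

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="Mutation")


def spectrum_table(
    sites: list[PolymorphicSite], regions: RegionMap
) -> SpectrumTable:
    """Aggregate site events into class x region counts."""
    region_labels = set(regions.labels)
    counts: dict[str, dict[str, int]] = {
        c: {r: 0 for r in regions.labels} for c in MUTATION_CLASSES
    }
    for site in sites:
        if site.region_label not in region_labels:
            raise ValueError(
                f"site at {site.position} has label {site.region_label!r}, "
                f"not in region map {regions.labels}"
            )
        for event in site.events:
            counts[event.class_name][site.region_label] += 1
    lengths = {r: regions.region_length(r) for r in regions.labels}
    return SpectrumTable(counts=counts, region_lengths=lengths)


def spectrum_from_counts(
    counts: dict[str, dict[str, int]], region_lengths: dict[str, int]
) -> SpectrumTable:
    """Build a table directly from per-class counts (e.g. a printed table)."""
    full = {c: {r: counts.get(c, {}).get(r, 0) for r in region_lengths} for c in MUTATION_CLASSES}
    return SpectrumTable(counts=full, region_lengths=dict(region_lengths))


def polymorphism_frequency(table: SpectrumTable, region: str) -> float:
    """Mutations per nucleotide of the region, in percent (exact value).

    For table output the value is conventionally truncated to one decimal
    (:func:`truncate_percent`).
    """
    length = table.region_lengths.get(region, 0)
    if length <= 0:
        raise ValueError(f"region {region!r} has zero length")
    return 100.0 * table.total(region) / length


# ---------------------------------------------------------------------------
# haplotype matrix


def haplotype_matrix(
    aln: MultipleAlignment, sites: list[PolymorphicSite]
) -> pd.DataFrame:
    """Sequence-by-site state matrix (rows: ids, columns: 1-based positions).

    For a merged indel site the state is the full run (bases or gaps), so a
    multi-base deletion reads as one state.
    """
    data: dict[int, list[str]] = {}
    for site in sites:
        states = []
        for _, seq in aln.records:
            states.append(seq[site.position - 1 : site.position - 1 + site.span])
        data[site.position] = states
    return pd.DataFrame(data, index=list(aln.ids))


def group_haplotypes(matrix: pd.DataFrame) -> list[tuple[tuple[str, ...], list[str]]]:
    """Group identical matrix rows; returns (pattern, member ids) pairs.

    Groups are ordered by first appearance, matching how variant tables
    list isolate groups.
    """
    groups: dict[tuple[str, ...], list[str]] = {}
    for rid, row in matrix.iterrows():
        key = tuple(row)
        groups.setdefault(key, []).append(str(rid))
    return [(pattern, members) for pattern, members in groups.items()]


def write_sites_tsv(sites: list[PolymorphicSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tregion\talleles\tevents\n")
        for s in sites:
            alleles = ",".join(f"{state}:{n}" for state, n in s.alleles)
            events = ";".join(
                f"{e.state_a}/{e.state_b}:{e.kind}" for e in s.events
            )
            fh.write(f"{s.position}\t{s.region_label}\t{alleles}\t{events}\n")
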