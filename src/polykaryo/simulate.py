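"""Synthetic cloned-amplicon datasets with ground truth.

The generator emulates the statistical structure of an intron-rich,
clone-sequenced amplicon locus sampled from fungal fruit bodies:

* a 586-nt coding region interleaved with four introns of 50-58 nt;
* intron per-column polymorphism density about nine times the exon
  density, with a C-T-transition-dominated substitution spectrum and
  short (1-4 nt) indels restricted to introns;
* a pool of parental haplotypes derived independently from one ancestral
  sequence (star genealogy: the downstream statistics use only the
  polymorphism structure, not genealogy depth);
* basidiomata formed from 2 or 3 parents drawn from the pool, with clone
  counts multinomially sampled at configurable proportions;
* per-clone PCR point errors (2:1:1 transition:transversion weighting) and
  PCR-mediated chimeras (single uniform template switch to another of the
  basidioma's parents);
* optional finite-island population structure via deme-private mutations,
  to produce tunable realized Fst.

Mutation model: at pool creation every alignment column (or, in introns,
run of 1-4 columns designated as an indel unit) is assigned one latent
biallelic event - a substitution class drawn from the configured spectrum
with an ancestor base compatible with it, or a deletion.  Each parent
independently carries the derived allele with a per-region probability
calibrated so the expected polymorphic fraction of the pool matches the
configured rates.  Recurrent carriage of the same derived allele by
several parents is therefore possible (homoplasy), as in the real locus.

Every emitted clone has exactly one provenance record in the truth
channel; identical seed and config give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import (
    MultipleAlignment,
    Region,
    RegionMap,
    SampleRow,
    SampleSheet,
)

__all__ = [
    "SimConfig",
    "SiteUnit",
    "SimTruth",
    "PoolSim",
    "SimDataset",
    "simulate_parental_pool",
    "simulate_basidioma",
    "simulate_dataset",
]

BASES = "ACGT"
TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS_OF = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: substitution-class weights of the emulated locus (exon / intron), plus
#: the share of intron variant units that are indels
EXON_CLASS_WEIGHTS = {"A-G": 5, "C-T": 22, "A-C": 2, "A-T": 1, "C-G": 2, "G-T": 0}
INTRON_CLASS_WEIGHTS = {"A-G": 7, "C-T": 44, "A-C": 9, "A-T": 12, "C-G": 6, "G-T": 7}
INTRON_INDEL_FRACTION = 12 / 97


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    seed: int
    exon_length: int = 586
    n_introns: int = 4
    intron_length_range: tuple[int, int] = (50, 58)
    exon_poly_rate: float = 0.054  # expected polymorphic fraction, exon columns
    intron_poly_rate: float = 0.468  # same, intron columns
    indel_length_range: tuple[int, int] = (1, 4)
    n_parental_pool: int = 20
    p_three_parents: float = 0.25
    clones_per_basidioma: int = 16
    clone_proportions_two: tuple[float, ...] = (0.5, 0.5)
    clone_proportions_three: tuple[float, ...] = (0.40, 0.35, 0.25)
    pcr_error_rate: float = 5e-5  # per base per clone
    chimera_rate: float = 0.02  # per clone
    n_basidiomata: int = 10
    n_populations: int = 3
    divergence: float = 0.0  # deme-private mutation prob per column

    def __post_init__(self) -> None:
        for name in ("exon_poly_rate", "intron_poly_rate", "pcr_error_rate",
                     "chimera_rate", "p_three_parents", "divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_parental_pool < 2:
            raise ValueError("n_parental_pool must be >= 2")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - fields
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
        }
        return cls(**kwargs)


@dataclass(frozen=True)
class SiteUnit:
    """One latent biallelic event: a column or an intron gap run."""

    position: int  # 1-based first column
    span: int  # 1 for substitutions, run length for indels
    region: str  # exon | intron
    kind: str  # transition | transversion | indel
    ancestral: str  # bases
    derived: str  # base or gaps


@dataclass
class SimTruth:
    """Ground truth: parents, clone provenance, injected errors."""

    ancestor: str = ""
    units: tuple[SiteUnit, ...] = ()
    parent_units: dict[str, tuple[int, ...]] = field(default_factory=dict)
    parents_of: dict[str, tuple[str, ...]] = field(default_factory=dict)
    clone_parent: dict[str, str] = field(default_factory=dict)
    chimera_of: dict[str, tuple[str, int]] = field(default_factory=dict)
    errors_of: dict[str, tuple[int, ...]] = field(default_factory=dict)
    population_of: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ancestor": self.ancestor,
            "units": [dataclasses.asdict(u) for u in self.units],
            "parent_units": {k: list(v) for k, v in self.parent_units.items()},
            "parents_of": {k: list(v) for k, v in self.parents_of.items()},
            "clone_parent": self.clone_parent,
            "chimera_of": {k: list(v) for k, v in self.chimera_of.items()},
            "errors_of": {k: list(v) for k, v in self.errors_of.items()},
            "population_of": self.population_of,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


@dataclass
class PoolSim:
    alignment: MultipleAlignment  # parental haplotypes P01..PK
    regions: RegionMap
    units: tuple[SiteUnit, ...]
    truth: SimTruth


@dataclass
class SimDataset:
    pool: PoolSim
    clones: MultipleAlignment
    sheet: SampleSheet
    truth: SimTruth

    @property
    def regions(self) -> RegionMap:
        return self.pool.regions


def _build_layout(config: SimConfig, rng: np.random.Generator) -> RegionMap:
    """Exon split into n_introns+1 segments interleaved with introns."""
    n_seg = config.n_introns + 1
    base, extra = divmod(config.exon_length, n_seg)
    exon_sizes = [base + (1 if i < extra else 0) for i in range(n_seg)]
    lo, hi = config.intron_length_range
    intron_sizes = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_introns)]
    regions = []
    pos = 1
    for i, size in enumerate(exon_sizes):
        regions.append(Region(pos, pos + size - 1, "exon"))
        pos += size
        if i < config.n_introns:
            isize = intron_sizes[i]
            regions.append(Region(pos, pos + isize - 1, "intron"))
            pos += isize
    return RegionMap(tuple(regions))


def _draw_class(weights: dict[str, int], rng: np.random.Generator) -> str:
    names = list(weights)
    w = np.array([weights[n] for n in names], float)
    return names[int(rng.choice(len(names), p=w / w.sum()))]


def _assign_units(
    config: SimConfig, regions: RegionMap, rng: np.random.Generator
) -> tuple[SiteUnit, ...]:
    lo, hi = config.indel_length_range
    mean_len = (lo + hi) / 2.0
    # per-column probability of starting an indel run such that the expected
    # share of intron variant units that are indels matches the target
    f = INTRON_INDEL_FRACTION
    indel_start_rate = f / (1 + (mean_len - 1) * f)

    units: list[SiteUnit] = []
    for reg in regions.regions:
        pos = reg.start
        while pos <= reg.end:
            if reg.label == "intron" and rng.random() < indel_start_rate:
                span = min(int(rng.integers(lo, hi + 1)), reg.end - pos + 1)
                anc = "".join(BASES[int(rng.integers(4))] for _ in range(span))
                units.append(
                    SiteUnit(pos, span, reg.label, "indel", anc, "-" * span)
                )
                pos += span
                continue
            weights = (
                EXON_CLASS_WEIGHTS if reg.label == "exon" else INTRON_CLASS_WEIGHTS
            )
            klass = _draw_class(weights, rng)
            a, b = klass.split("-")
            if rng.random() < 0.5:
                a, b = b, a
            kind = "transition" if klass in ("A-G", "C-T") else "transversion"
            units.append(SiteUnit(pos, 1, reg.label, kind, a, b))
            pos += 1
    return tuple(units)


def _carry_probability(
    rate: float, n_columns: int, n_units: int, pool_size: int
) -> float:
    """Per-parent derived-allele probability for one region.

    Calibrated so the expected number of polymorphic units equals
    ``rate * n_columns`` (indel-run merging makes units fewer than
    columns, so the per-unit rate is inflated accordingly).
    """
    unit_rate = min(rate * n_columns / max(n_units, 1), 0.95)
    return 1.0 - (1.0 - unit_rate) ** (1.0 / pool_size)


def simulate_parental_pool(
    config: SimConfig, rng: np.random.Generator | None = None
) -> PoolSim:
    """Draw the ancestral sequence and mutate it into the parental pool."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    regions = _build_layout(config, rng)
    units = _assign_units(config, regions, rng)

    length = regions.length
    ancestor = [BASES[int(i)] for i in rng.integers(4, size=length)]
    for u in units:  # make the ancestor consistent with each unit's allele
        ancestor[u.position - 1 : u.position - 1 + u.span] = list(u.ancestral)
    ancestor_s = "".join(ancestor)

    carry = {}
    for label in regions.labels:
        n_cols = regions.region_length(label)
        n_units = sum(1 for u in units if u.region == label)
        rate = config.exon_poly_rate if label == "exon" else config.intron_poly_rate
        carry[label] = _carry_probability(rate, n_cols, n_units, config.n_parental_pool)

    truth = SimTruth(ancestor=ancestor_s, units=units)
    records = []
    width = max(2, len(str(config.n_parental_pool)))
    for i in range(config.n_parental_pool):
        pid = f"P{i + 1:0{width}d}"
        seq = list(ancestor_s)
        carried = []
        for j, u in enumerate(units):
            if rng.random() < carry[u.region]:
                seq[u.position - 1 : u.position - 1 + u.span] = list(u.derived)
                carried.append(j)
        records.append((pid, "".join(seq)))
        truth.parent_units[pid] = tuple(carried)
    pool_aln = MultipleAlignment(tuple(records))
    return PoolSim(alignment=pool_aln, regions=regions, units=units, truth=truth)


def _pcr_errors(
    seq: list[str], rate: float, rng: np.random.Generator
) -> list[int]:
    """Inject point errors in place; returns 1-based error positions.

    Errors hit bases only (never gaps) with 2:1:1 weighting: the transition
    of the template base twice as likely as either transversion.
    """
    if rate <= 0:
        return []
    n_hits = rng.binomial(len(seq), rate)
    positions: list[int] = []
    for _ in range(n_hits):
        pos = int(rng.integers(len(seq)))
        if seq[pos] not in BASES:
            continue
        r = rng.random()
        if r < 0.5:
            seq[pos] = TRANSITION_OF[seq[pos]]
        else:
            seq[pos] = TRANSVERSIONS_OF[seq[pos]][int(r < 0.75)]
        positions.append(pos + 1)
    return sorted(positions)


def simulate_basidioma(
    pool: PoolSim,
    config: SimConfig,
    basidioma_id: str,
    rng: np.random.Generator,
    locality: str = "loc1",
    parent_ids: tuple[str, ...] | None = None,
    proportions: tuple[float, ...] | None = None,
) -> tuple[list[tuple[str, str]], list[SampleRow], SimTruth]:
    """Sample one basidioma's clones from the pool.

    Parents are drawn without replacement (2 or 3, per the configured
    mixture) unless ``parent_ids`` pins them; clone counts are multinomial
    at the configured proportions.  Each clone copies its parent, may
    become a chimera (single template switch to another of the basidioma's
    parents at a uniform breakpoint) and then acquires PCR point errors.
    Returns clone records, sample-sheet rows and a truth fragment.
    """
    pool_ids = list(pool.alignment.ids)
    if parent_ids is None:
        k = 3 if rng.random() < config.p_three_parents else 2
        chosen = rng.choice(len(pool_ids), size=k, replace=False)
        parent_ids = tuple(pool_ids[int(i)] for i in chosen)
    k = len(parent_ids)
    if proportions is None:
        proportions = (
            config.clone_proportions_two if k == 2 else config.clone_proportions_three
        )
    if len(proportions) != k:
        raise ValueError("proportions length must match number of parents")
    p = np.array(proportions, float)
    counts = rng.multinomial(config.clones_per_basidioma, p / p.sum())

    truth = SimTruth(parents_of={basidioma_id: parent_ids})
    clones: list[tuple[str, str]] = []
    rows: list[SampleRow] = []
    clone_no = 0
    for pid, n_clones in zip(parent_ids, counts):
        for _ in range(int(n_clones)):
            clone_no += 1
            cid = f"{basidioma_id}_c{clone_no:02d}"
            seq = list(pool.alignment[pid])
            truth.clone_parent[cid] = pid
            if k > 1 and rng.random() < config.chimera_rate:
                others = [q for q in parent_ids if q != pid]
                partner = others[int(rng.integers(len(others)))]
                breakpoint = int(rng.integers(1, len(seq)))
                seq[breakpoint:] = list(pool.alignment[partner])[breakpoint:]
                truth.chimera_of[cid] = (partner, breakpoint)
            errors = _pcr_errors(seq, config.pcr_error_rate, rng)
            if errors:
                truth.errors_of[cid] = tuple(errors)
            clones.append((cid, "".join(seq)))
            rows.append(SampleRow(cid, basidioma_id, locality, 1))
    return clones, rows, truth


def _merge_truth(base: SimTruth, fragment: SimTruth) -> None:
    base.parents_of.update(fragment.parents_of)
    base.clone_parent.update(fragment.clone_parent)
    base.chimera_of.update(fragment.chimera_of)
    base.errors_of.update(fragment.errors_of)
    base.population_of.update(fragment.population_of)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Full dataset: pool, basidiomata allocated to demes, clones, truth.

    With ``divergence > 0`` each deme receives private substitutions
    applied to its copy of every pool parent (finite-island structure);
    with the default 0 all demes share one panmictic pool.
    """
    rng = np.random.default_rng(config.seed)
    pool = simulate_parental_pool(config, rng)
    demes = [f"pop{i + 1}" for i in range(config.n_populations)]

    deme_pools: dict[str, PoolSim] = {}
    for deme in demes:
        if config.divergence > 0:
            deme_pools[deme] = _diverge_pool(pool, config, rng)
        else:
            deme_pools[deme] = pool

    truth = SimTruth(ancestor=pool.truth.ancestor, units=pool.units,
                     parent_units=dict(pool.truth.parent_units))
    all_clones: list[tuple[str, str]] = []
    all_rows: list[SampleRow] = []
    for b in range(config.n_basidiomata):
        bid = f"G{b + 1:02d}"
        deme = demes[int(rng.integers(len(demes)))]
        truth.population_of[bid] = deme
        clones, rows, frag = simulate_basidioma(
            deme_pools[deme], config, bid, rng, locality=deme
        )
        _merge_truth(truth, frag)
        all_clones.extend(clones)
        all_rows.extend(rows)
    return SimDataset(
        pool=pool,
        clones=MultipleAlignment(tuple(all_clones)),
        sheet=SampleSheet(tuple(all_rows)),
        truth=truth,
    )


def _diverge_pool(
    pool: PoolSim, config: SimConfig, rng: np.random.Generator
) -> PoolSim:
    """Deme-private substitutions shared by every parent of the deme copy."""
    length = pool.alignment.length
    hit = rng.random(length) < config.divergence
    changes = {}
    for pos in np.flatnonzero(hit):
        base = pool.truth.ancestor[pos]
        if base in BASES:
            alts = [b for b in BASES if b != base]
            changes[int(pos)] = alts[int(rng.integers(3))]
    records = []
    for pid, seq in pool.alignment.records:
        s = list(seq)
        for pos, alt in changes.items():
            if s[pos] in BASES:
                s[pos] = alt
        records.append((pid, "".join(s)))
    return PoolSim(
        alignment=MultipleAlignment(tuple(records)),
        regions=pool.regions,
        units=pool.units,
        truth=pool.truth,
    )
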