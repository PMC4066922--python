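"""End-to-end orchestration of the clone-haplotype analysis.

``run_pipeline`` chains the stages — alignment/region/sheet loading,
polymorphic-site detection and spectrum, per-basidioma haplotype calling
with the singleton rule and parent-count decision, per-minor crossover
analysis, the PHI recombination test, gene diversity / Fst across
localities and the haplotype network — and writes TSV/JSON reports plus a
run manifest.  Floating-point output is rounded to six decimals so reruns
with the same seed and config produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .clone_haplotypes import (
    DOMINANT,
    MINOR_SUPPORTED,
    ErrorModel,
    HaplotypeCall,
    ParentCountCall,
    call_parent_count,
    collapse_clones,
    filter_singletons,
)
from .polymorphism import (
    find_polymorphic_sites,
    haplotype_matrix,
    polymorphism_frequency,
    spectrum_table,
    truncate_percent,
    write_sites_tsv,
)
from .popgen import build_network, gene_diversity_fst
from .recombination import CrossoverResult, min_crossovers, phi_test
from .seqio import (
    MultipleAlignment,
    RegionMap,
    SampleSheet,
    partition_alignment,
    read_alignment,
    read_regions,
    read_sample_sheet,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "BasidiomaAnalysis", "analyze_basidioma", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Inputs and stage parameters; defaults equal the module defaults."""

    alignment: str
    regions: str
    sample_sheet: str
    out_dir: str = "polykaryo_out"
    min_support: int = 2
    alpha: float = 0.05
    max_crossovers_recent: int = 2
    window: int = 100
    permutations: int = 1000
    estimator: str = "wc_theta"
    network_method: str = "msn"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - fields
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class BasidiomaAnalysis:
    basidioma_id: str
    calls: list[HaplotypeCall]
    crossovers: dict[str, CrossoverResult]
    parent_call: ParentCountCall


def analyze_basidioma(
    aln: MultipleAlignment,
    sheet: SampleSheet,
    basidioma_id: str,
    *,
    min_support: int = 2,
    alpha: float = 0.05,
    max_crossovers_recent: int = 2,
    error_model: ErrorModel | None = None,
) -> BasidiomaAnalysis:
    """Collapse, filter and call the parent count for one basidioma.

    Every minor supported haplotype is additionally analysed as a
    candidate recombinant of the dominant pair (minimal template
    switches).
    """
    group = collapse_clones(aln, sheet, basidioma_id)
    calls = filter_singletons(group, min_support=min_support)
    dominants = [c for c in calls if c.status == DOMINANT]
    minors = [c for c in calls if c.status == MINOR_SUPPORTED]
    crossovers: dict[str, CrossoverResult] = {}
    if len(dominants) == 2:
        parents = [
            (c.haplotype.haplotype_id, c.haplotype.sequence) for c in dominants
        ]
        for c in minors:
            try:
                crossovers[c.haplotype.haplotype_id] = min_crossovers(
                    (c.haplotype.haplotype_id, c.haplotype.sequence), parents
                )
            except ValueError:
                logger.warning(
                    "dominant haplotypes of %s are identical at every site; "
                    "skipping crossover analysis for %s",
                    basidioma_id,
                    c.haplotype.haplotype_id,
                )
    parent_call = call_parent_count(
        group,
        calls,
        crossovers,
        error_model=error_model,
        alpha=alpha,
        max_crossovers_recent=max_crossovers_recent,
    )
    return BasidiomaAnalysis(basidioma_id, calls, crossovers, parent_call)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the parent-call summary as a dict (also written as JSON).
    Raises on missing inputs or invariant violations; the CLI converts
    those into a nonzero exit status.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    aln = read_alignment(config.alignment)
    regions = read_regions(config.regions, aln.length)
    sheet = read_sample_sheet(config.sample_sheet)
    sheet.validate_against(aln)

    # polymorphism stage
    sites = find_polymorphic_sites(aln, regions)
    write_sites_tsv(sites, out / "sites.tsv")
    table = spectrum_table(sites, regions)
    table.to_tsv(out / "spectrum.tsv")
    frequencies = {
        label: truncate_percent(polymorphism_frequency(table, label))
        for label in regions.labels
        if regions.region_length(label) > 0
    }

    # clone stage
    analyses = [
        analyze_basidioma(
            aln,
            sheet,
            bid,
            min_support=config.min_support,
            alpha=config.alpha,
            max_crossovers_recent=config.max_crossovers_recent,
        )
        for bid in sheet.basidioma_ids
    ]
    _write_haplotype_report(analyses, out / "haplotypes.tsv")
    _write_crossover_report(analyses, out / "crossovers.tsv")
    parent_calls = {
        a.basidioma_id: {
            "n_parents": a.parent_call.n_parents,
            "evidence": list(a.parent_call.evidence),
        }
        for a in analyses
    }

    # retained haplotypes, one per basidioma each (haploid popgen units)
    retained: list[tuple[str, str, str]] = []  # (uid, sequence, locality)
    for a in analyses:
        for c in a.calls:
            if c.status in (DOMINANT, MINOR_SUPPORTED):
                retained.append(
                    (
                        f"{a.basidioma_id}:{c.haplotype.haplotype_id}",
                        c.haplotype.sequence,
                        sheet.locality_of(a.basidioma_id),
                    )
                )

    # recombination stage: PHI over the retained haplotypes
    phi = None
    if len(retained) >= 4:
        hap_aln = MultipleAlignment(tuple((u, s) for u, s, _ in retained))
        phi = phi_test(
            hap_aln,
            window=config.window,
            n_permutations=config.permutations,
            seed=config.seed,
        )

    # diversity on exon haplotypes across localities
    diversity = None
    exon_haps = [
        (_exon_seq(seq, regions), loc) for _, seq, loc in retained
    ]
    if len({loc for _, loc in exon_haps}) >= 2:
        diversity = gene_diversity_fst(
            [h for h, _ in exon_haps],
            [loc for _, loc in exon_haps],
            estimator=config.estimator,
            seed=config.seed,
        )

    # haplotype network over distinct retained haplotypes
    network = None
    if retained:
        hap_aln = MultipleAlignment(tuple((u, s) for u, s, _ in retained))
        hap_sites = find_polymorphic_sites(hap_aln, regions)
        if hap_sites:
            matrix = haplotype_matrix(hap_aln, hap_sites)
            network = build_network(matrix, method=config.network_method)
            network.to_edge_tsv(out / "network_edges.tsv")

    report = {
        "n_polymorphic_sites": len(sites),
        "polymorphism_frequency_percent": frequencies,
        "parent_calls": parent_calls,
        "phi": None
        if phi is None
        else {
            "statistic": phi.statistic,
            "p_value": phi.p_value,
            "n_informative": phi.n_informative,
            "computable": phi.computable,
        },
        "diversity": None
        if diversity is None
        else {
            "estimator": diversity.estimator,
            "fst": diversity.fst,
            "sd_fst": diversity.sd_fst,
            "hs": diversity.hs,
            "ht": diversity.ht,
        },
        "network_nodes": None if network is None else network.n_nodes,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True)

    manifest = {
        "polykaryo_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report


def _exon_seq(seq: str, regions: RegionMap) -> str:
    return "".join(seq[p - 1] for p in regions.columns("exon"))


def _write_haplotype_report(analyses: list[BasidiomaAnalysis], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "basidioma\thaplotype_id\tsupport\tstatus\t"
            "unique_polymorphisms\tshared_error_p\n"
        )
        for a in analyses:
            minors = {
                e["haplotype"]: e
                for e in a.parent_call.evidence
                if "haplotype" in e and e["status"] == MINOR_SUPPORTED
            }
            for c in a.calls:
                hid = c.haplotype.haplotype_id
                extra = minors.get(hid, {})
                uniq = extra.get("unique_polymorphisms", "")
                p = extra.get("shared_error_p", "")
                if isinstance(p, float):
                    p = f"{p:.6g}"
                fh.write(
                    f"{a.basidioma_id}\t{hid}\t{c.haplotype.support}\t"
                    f"{c.status}\t{uniq}\t{p}\n"
                )


def _write_crossover_report(analyses: list[BasidiomaAnalysis], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "basidioma\tchild\tparents\tk_switches\tbreakpoints\tunexplained\n"
        )
        for a in analyses:
            for hid, res in a.crossovers.items():
                bps = ";".join(f"{x}-{y}" for x, y in res.breakpoint_intervals)
                unexp = ",".join(str(p) for p in res.unexplained_sites)
                fh.write(
                    f"{a.basidioma_id}\t{hid}\t{'|'.join(res.parent_ids)}\t"
                    f"{res.k_switches}\t{bps}\t{unexp}\n"
                )
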