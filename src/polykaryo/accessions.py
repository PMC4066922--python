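"""Checks against the deposited clone sequences of the original study.

The tef1α clone haplotypes behind this analysis are deposited as GenBank
KF746962-KF746998.  Downloading them is a user step (this package performs
no network access): align them (e.g. with MAFFT), export the alignment as
FASTA, write a BED region file for the exon/intron layout and a sample
sheet with the per-accession clone counts, and point
:func:`run_accession_checks` at the three files.

The checks recompute, on the real data, the quantities the desk datasets
can only emulate: the 586-nt exon concatenation, the per-basidioma
pairwise polymorphism counts of the multi-haplotype fruit bodies, the PHI
recombination p-value over all retained haplotypes and the exon-haplotype
Fst across the three collection localities.
"""

from __future__ import annotations

from pathlib import Path

from .clone_haplotypes import DOMINANT, MINOR_SUPPORTED
from .pipeline import analyze_basidioma
from .polymorphism import find_polymorphic_sites
from .recombination import phi_test
from .popgen import gene_diversity_fst
from .seqio import (
    MultipleAlignment,
    partition_alignment,
    read_alignment,
    read_regions,
    read_sample_sheet,
)

__all__ = ["DEFAULT_ACCESSION_FASTA", "run_accession_checks"]

#: conventional location for the user-supplied accession alignment
DEFAULT_ACCESSION_FASTA = Path("data/accessions/tef1a_clones.fasta")


def polymorphism_count(aln: MultipleAlignment, regions) -> int:
    """Number of polymorphism events among the given haplotypes."""
    sites = find_polymorphic_sites(aln, regions)
    return sum(len(s.events) for s in sites)


def run_accession_checks(
    alignment_path: str | Path,
    regions_path: str | Path,
    sheet_path: str | Path,
    *,
    seed: int = 0,
    window: int = 100,
    permutations: int = 1000,
) -> dict:
    """Recompute the study's headline quantities from deposited data.

    Returns a dict with the exon alignment length, per-basidioma retained
    haplotype counts and pairwise polymorphism counts, the PHI p-value and
    the exon Fst across localities.
    """
    aln = read_alignment(alignment_path)
    regions = read_regions(regions_path, aln.length)
    sheet = read_sample_sheet(sheet_path)
    sheet.validate_against(aln)

    exon = partition_alignment(aln, regions, keep="exon")
    results: dict = {"exon_length": exon.length, "basidiomata": {}}

    retained: list[tuple[str, str, str]] = []
    for bid in sheet.basidioma_ids:
        analysis = analyze_basidioma(aln, sheet, bid)
        kept = [
            c
            for c in analysis.calls
            if c.status in (DOMINANT, MINOR_SUPPORTED)
        ]
        entry: dict = {
            "n_retained": len(kept),
            "n_parents": analysis.parent_call.n_parents,
        }
        if len(kept) >= 2:
            sub = MultipleAlignment(
                tuple((c.haplotype.haplotype_id, c.haplotype.sequence) for c in kept)
            )
            entry["pairwise_polymorphisms"] = polymorphism_count(sub, regions)
        results["basidiomata"][bid] = entry
        for c in kept:
            retained.append(
                (
                    f"{bid}:{c.haplotype.haplotype_id}",
                    c.haplotype.sequence,
                    sheet.locality_of(bid),
                )
            )

    hap_aln = MultipleAlignment(tuple((u, s) for u, s, _ in retained))
    phi = phi_test(hap_aln, window=window, n_permutations=permutations, seed=seed)
    results["phi_p_value"] = phi.p_value

    exon_haps = [
        ("".join(s[p - 1] for p in regions.columns("exon")), loc)
        for _, s, loc in retained
    ]
    div = gene_diversity_fst(
        [h for h, _ in exon_haps], [loc for _, loc in exon_haps], seed=seed
    )
    results["fst"] = div.fst
    results["sd_fst"] = div.sd_fst
    return results
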