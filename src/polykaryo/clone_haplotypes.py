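"""Per-basidioma haplotype calling from cloned amplicon sequences.

Each basidioma (fruit body) yields a set of plasmid-cloned PCR amplicons,
each sequenced once.  Identical clone sequences are collapsed into
haplotypes with support counts; haplotypes supported by a single clone are
excluded as possible cloning/PCR artefacts; the two best-supported retained
haplotypes are the *dominant* pair (the dikaryon null expectation).  Any
further retained haplotype is a candidate third parent and is accepted as
one only if (a) its defining mutations are unlikely to recur by chance
under a birthday-paradox error model and (b) it is not explainable as a
recent recombinant (template switch) of the dominant pair.

Shared-error model
------------------
Treat each clone as acquiring at most one random error, landing uniformly
on one of the ``L`` polymorphic regions of the basidioma's alignment with
relative class weights transition : transversion : transversion = 2 : 1 : 1
(a transition is twice as likely as either specific transversion).  The
probability that one *specific* transition recurs in >= k of n clones is
approximated by the leading binomial term

    P(>=k) ~= C(n, k) * q^k,        q = 1 / (2 L)

and, per the conventional halving rule, the probability for a specific
transversion is half the transition value.  Two exact alternatives are
exposed: ``variant="weighted"`` uses q = w / (4 L) with w = 2 (transition)
or 1 (transversion), the expected number of k-clone coincidences; and
``variant="binomial_tail"`` evaluates the full tail
sum_{j>=k} C(n,j) q^j (1-q)^(n-j).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import TYPE_CHECKING, Sequence

from .polymorphism import classify_mutation
from .seqio import MultipleAlignment, SampleSheet

if TYPE_CHECKING:  # pragma: no cover
    from .recombination import CrossoverResult

__all__ = [
    "Haplotype",
    "CloneGroup",
    "HaplotypeCall",
    "ErrorModel",
    "ParentCountCall",
    "collapse_clones",
    "filter_singletons",
    "shared_error_probability",
    "call_parent_count",
]

DOMINANT = "dominant"
MINOR_SUPPORTED = "minor_supported"
SINGLETON_EXCLUDED = "singleton_excluded"


@dataclass(frozen=True)
class Haplotype:
    haplotype_id: str
    sequence: str
    support: int
    members: tuple[str, ...]


@dataclass(frozen=True)
class CloneGroup:
    """Collapsed clone sequences of one basidioma.

    Haplotypes are sorted by descending support, ties by smallest member
    sequence id.
    """

    basidioma_id: str
    haplotypes: tuple[Haplotype, ...]
    total_clones: int

    def __post_init__(self) -> None:
        if sum(h.support for h in self.haplotypes) != self.total_clones:
            raise ValueError("supports do not sum to total_clones")
        seqs = [h.sequence for h in self.haplotypes]
        if len(set(seqs)) != len(seqs):
            raise ValueError("haplotype sequences are not pairwise distinct")


@dataclass(frozen=True)
class HaplotypeCall:
    haplotype: Haplotype
    status: str  # dominant | minor_supported | singleton_excluded
    unique_polymorphisms: int = 0
    shared_error_p: float = 1.0


@dataclass(frozen=True)
class ErrorModel:
    """Birthday-paradox error model parameters.

    ``n_clones``: clones sequenced for the basidioma; ``n_polymorphic_regions``:
    number of polymorphic sites L over which a random error can land;
    ``variant``: ``"halved"`` (default), ``"weighted"`` or ``"binomial_tail"``
    (see module docstring).
    """

    n_clones: int
    n_polymorphic_regions: int
    variant: str = "halved"

    def __post_init__(self) -> None:
        if self.n_clones < 1 or self.n_polymorphic_regions < 1:
            raise ValueError("n_clones and n_polymorphic_regions must be >= 1")
        if self.variant not in ("halved", "weighted", "binomial_tail"):
            raise ValueError(f"unknown variant {self.variant!r}")


def shared_error_probability(
    model: ErrorModel, k: int, mutation_class: str
) -> float:
    """Probability that one specific mutation recurs in >= k of n clones.

    ``mutation_class`` is ``"transition"`` or ``"transversion"``; the
    transversion value is exactly half the transition value under the
    default variant.  ``k = 1`` returns 1.0 (a single occurrence requires
    no coincidence); ``k > n_clones`` returns 0.0.
    """
    if mutation_class not in ("transition", "transversion"):
        raise ValueError(f"unknown mutation class {mutation_class!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    n, L = model.n_clones, model.n_polymorphic_regions
    if k > n:
        return 0.0
    if k == 1:
        return 1.0
    if model.variant == "halved":
        q = 1.0 / (2 * L)  # transition hit probability per clone
        p = comb(n, k) * q**k
        if mutation_class == "transversion":
            p /= 2.0
    else:
        w = 2.0 if mutation_class == "transition" else 1.0
        q = w / (4.0 * L)
        if model.variant == "weighted":
            p = comb(n, k) * q**k
        else:  # binomial_tail
            p = sum(
                comb(n, j) * q**j * (1.0 - q) ** (n - j) for j in range(k, n + 1)
            )
    return min(p, 1.0)


def collapse_clones(
    aln: MultipleAlignment, sheet: SampleSheet, basidioma_id: str
) -> CloneGroup:
    """Collapse the basidioma's clone sequences by exact string match.

    Each sample-sheet row contributes ``clone_count`` identical clones, so
    pre-collapsed inputs (one row per deposited haplotype, count in the
    sheet) and raw one-row-per-clone inputs both work.
    """
    rows = sheet.rows_for(basidioma_id)
    by_seq: dict[str, list] = {}
    for row in rows:
        seq = aln[row.seq_id]
        by_seq.setdefault(seq, []).append(row)
    haplotypes = []
    for seq, members in by_seq.items():
        support = sum(r.clone_count for r in members)
        ids = tuple(sorted(r.seq_id for r in members))
        haplotypes.append(
            Haplotype(haplotype_id=ids[0], sequence=seq, support=support, members=ids)
        )
    haplotypes.sort(key=lambda h: (-h.support, h.haplotype_id))
    total = sum(r.clone_count for r in rows)
    return CloneGroup(
        basidioma_id=basidioma_id, haplotypes=tuple(haplotypes), total_clones=total
    )


def filter_singletons(
    group: CloneGroup, min_support: int = 2
) -> list[HaplotypeCall]:
    """Apply the singleton-exclusion rule and mark the dominant pair.

    Haplotypes with support below ``min_support`` are excluded as possible
    cloning errors; of the retained, the two best-supported are dominant
    (ties broken by haplotype id, i.e. the sort order of the group) and the
    rest are minor but supported.  An empty retained set is allowed; the
    basidioma is then uncallable downstream.
    """
    calls: list[HaplotypeCall] = []
    retained = 0
    for hap in group.haplotypes:  # already sorted by support desc, id asc
        if hap.support < min_support:
            status = SINGLETON_EXCLUDED
        elif retained < 2:
            status = DOMINANT
            retained += 1
        else:
            status = MINOR_SUPPORTED
        calls.append(HaplotypeCall(haplotype=hap, status=status))
    return calls


@dataclass(frozen=True)
class ParentCountCall:
    basidioma_id: str
    n_parents: int | None  # None = uncallable (no retained haplotypes)
    evidence: tuple[dict, ...] = field(default_factory=tuple)

    @property
    def callable(self) -> bool:
        return self.n_parents is not None


def _unique_mutations(
    minor_seq: str, dominant_seqs: Sequence[str]
) -> list[tuple[int, str]]:
    """(position, class) of sites where the minor matches NO dominant.

    Gap/base differences classify as indels; sites where any sequence has N
    are skipped.
    """
    out = []
    for i, c in enumerate(minor_seq):
        dom_states = {s[i] for s in dominant_seqs}
        if c == "N" or "N" in dom_states:
            continue
        if c not in dom_states:
            # classify against the first dominant state, alphabetically
            other = sorted(dom_states)[0]
            kind = classify_mutation(c if c != "-" else "-", other)
            out.append((i + 1, kind))
    return out


def call_parent_count(
    group: CloneGroup,
    calls: list[HaplotypeCall],
    crossover_results: dict[str, "CrossoverResult"] | None = None,
    *,
    error_model: ErrorModel | None = None,
    alpha: float = 0.05,
    max_crossovers_recent: int = 2,
) -> ParentCountCall:
    """Call the number of parental haplotypes behind one basidioma.

    A minor supported haplotype counts as an additional parent iff its
    unique polymorphisms (sites matching no dominant haplotype) have a
    joint shared-error probability below ``alpha`` AND it cannot be
    explained as a recombinant of the dominant pair with at most
    ``max_crossovers_recent`` template switches and zero unexplained sites.
    ``crossover_results`` maps minor haplotype ids to their
    :class:`~polykaryo.recombination.CrossoverResult` against the dominant
    pair; required whenever there are minors and two dominants.

    ``error_model`` defaults to n = total clones of the basidioma and L =
    the number of polymorphic sites among the group's haplotypes.
    """
    dominants = [c for c in calls if c.status == DOMINANT]
    minors = [c for c in calls if c.status == MINOR_SUPPORTED]
    evidence: list[dict] = []

    if not dominants:
        return ParentCountCall(group.basidioma_id, None, (
            {"note": "no haplotype retained after singleton exclusion"},
        ))

    if error_model is None:
        L = _n_polymorphic_sites([h.sequence for h in group.haplotypes])
        error_model = ErrorModel(
            n_clones=group.total_clones, n_polymorphic_regions=max(L, 1)
        )

    n_parents = len(dominants)
    for call in dominants:
        evidence.append(
            {
                "haplotype": call.haplotype.haplotype_id,
                "support": call.haplotype.support,
                "status": DOMINANT,
            }
        )
    if len(dominants) == 1:
        evidence.append(
            {
                "note": (
                    "single retained haplotype: parents may be homozygous at "
                    "this locus or a second parent went undetected"
                )
            }
        )

    dom_seqs = [c.haplotype.sequence for c in dominants]
    for call in minors:
        uniq = _unique_mutations(call.haplotype.sequence, dom_seqs)
        joint_p = 1.0
        for _, kind in uniq:
            if kind == "indel":
                kind = "transversion"  # conservative: rare class, halved P
            joint_p *= shared_error_probability(
                error_model, call.haplotype.support, kind
            )
        if not uniq:
            joint_p = 1.0

        recomb_explained = False
        xover = None
        if crossover_results is not None:
            xover = crossover_results.get(call.haplotype.haplotype_id)
        if xover is not None:
            recomb_explained = (
                xover.k_switches <= max_crossovers_recent
                and not xover.unexplained_sites
            )
        elif len(dom_seqs) >= 2:
            raise ValueError(
                f"crossover result missing for minor haplotype "
                f"{call.haplotype.haplotype_id!r}"
            )

        is_parent = joint_p < alpha and not recomb_explained
        if is_parent:
            n_parents += 1
        evidence.append(
            {
                "haplotype": call.haplotype.haplotype_id,
                "support": call.haplotype.support,
                "status": MINOR_SUPPORTED,
                "unique_polymorphisms": len(uniq),
                "shared_error_p": joint_p,
                "recombinant_of_dominants": recomb_explained,
                "counted_as_parent": is_parent,
            }
        )

    for call in calls:
        if call.status == SINGLETON_EXCLUDED:
            evidence.append(
                {
                    "haplotype": call.haplotype.haplotype_id,
                    "support": call.haplotype.support,
                    "status": SINGLETON_EXCLUDED,
                }
            )

    return ParentCountCall(group.basidioma_id, n_parents, tuple(evidence))


def _n_polymorphic_sites(seqs: list[str]) -> int:
    """Columns where the haplotype sequences are not all identical."""
    if len(seqs) < 2:
        return 0
    n = 0
    for states in zip(*seqs):
        distinct = {s for s in states if s != "N"}
        if len(distinct) > 1:
            n += 1
    return n
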