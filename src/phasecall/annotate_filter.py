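"""Site annotations and the two filter policies.

Annotations: homopolymer context, low per-base coverage, high in-read
deletion fraction, strand imbalance (an exact-binomial analog of the
SRP/SAP statistics), low QUAL, and phase inconsistency (low PE).

Policies: ``qual-contamination`` keeps sites passing the QUAL threshold
only; ``phasing-heuristics`` additionally drops het calls that fail the
phase-entropy or strand checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

from .formats_io import Genotype, PileupCounts, VariantSite

POLICY_QUAL = "qual-contamination"
POLICY_PHASING = "phasing-heuristics"


@dataclass
class FilterPolicy:
    name: str = POLICY_QUAL
    qual_threshold: float = 100.0
    coverage_floor: int = 40
    deletion_ceiling: float = 0.40
    homopolymer_len: int = 5
    strand_phred_threshold: float = 30.0
    pe_threshold: float = 2.5
    enabled_flags: set[str] = field(
        default_factory=lambda: {
            "homopolymer",
            "low-coverage",
            "high-deletion",
            "strand-bias",
            "low-qual",
            "bad-phasing",
        }
    )

    def __post_init__(self) -> None:
        if self.name not in (POLICY_QUAL, POLICY_PHASING, "custom"):
            raise ValueError(f"unknown policy {self.name!r}")
        for attr in ("qual_threshold", "coverage_floor", "deletion_ceiling",
                     "homopolymer_len", "strand_phred_threshold"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")


def _homopolymer_runs(reference: str, min_len: int):
    """(start, end) 1-based inclusive spans of maximal runs >= min_len."""
    arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    if arr.size == 0:
        return []
    change = np.nonzero(np.diff(arr) != 0)[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [arr.size - 1]])
    keep = (ends - starts + 1) >= min_len
    return list(zip(starts[keep] + 1, ends[keep] + 1))


def annotate_homopolymer(reference: str, pos: int, min_len: int = 5) -> bool:
    """True when a 1-based position lies within or immediately flanks a
    maximal single-base run of at least ``min_len`` bases.

    Flanking bases are included because deletion-driven misalignment at a
    run perturbs calls at its boundaries as well.
    """
    if not 1 <= pos <= len(reference):
        raise IndexError(f"position {pos} outside reference of length {len(reference)}")
    for start, end in _homopolymer_runs(reference, min_len):
        if start - 1 <= pos <= end + 1:
            return True
    return False


def homopolymer_flags(reference: str, positions, min_len: int = 5) -> np.ndarray:
    """Vectorized :func:`annotate_homopolymer` over many positions."""
    positions = np.asarray(positions)
    flagged = np.zeros(len(reference) + 2, dtype=bool)
    for start, end in _homopolymer_runs(reference, min_len):
        flagged[max(start - 1, 0) : end + 2] = True
    return flagged[positions]


def strand_bias_phred(n_fwd: int, n_rev: int) -> float:
    """Phred-scaled two-sided exact binomial(0.5) strand-imbalance score.

    0 for perfect balance, large for strong bias.
    """
    n = n_fwd + n_rev
    if n == 0:
        return 0.0
    p = binomtest(n_fwd, n, 0.5).pvalue
    return float(-10.0 * np.log10(max(p, 1e-300)))


def annotate_site(
    counts: PileupCounts,
    site: VariantSite,
    policy: FilterPolicy,
    pe: float | None = None,
    reference: str | None = None,
) -> set[str]:
    """Compute the annotation battery for one site."""
    flags: set[str] = set()
    if counts.coverage < policy.coverage_floor:
        flags.add("low-coverage")
    if counts.physical_coverage > 0 and counts.deletion_fraction >= policy.deletion_ceiling:
        flags.add("high-deletion")
    srp = strand_bias_phred(counts.ref_fwd, counts.ref_rev)
    sap = strand_bias_phred(counts.alt_fwd, counts.alt_rev)
    if max(srp, sap) >= policy.strand_phred_threshold:
        flags.add("strand-bias")
    if site.qual < policy.qual_threshold:
        flags.add("low-qual")
    if pe is None:
        pe = site.pe
    if pe is not None and pe < policy.pe_threshold:
        flags.add("bad-phasing")
    if reference is not None and annotate_homopolymer(
        reference, site.pos, policy.homopolymer_len
    ):
        flags.add("homopolymer")
    return flags & policy.enabled_flags


def annotate_sites(
    sites: list[VariantSite],
    policy: FilterPolicy,
    reference: str | None = None,
) -> None:
    """Annotate in place; uses each site's stored pileup counts and PE."""
    hp = None
    if reference is not None and sites:
        hp = homopolymer_flags(
            reference, [s.pos for s in sites], policy.homopolymer_len
        )
    for i, s in enumerate(sites):
        counts = s.info.get("counts")
        if counts is None:
            counts = PileupCounts()
        s.annotations = annotate_site(counts, s, policy)
        if hp is not None and hp[i]:
            s.annotations.add("homopolymer")


@dataclass
class FilterReport:
    kept: list[VariantSite]
    removed: list[VariantSite]
    removal_counts: dict[str, int]


def apply_policy(sites: list[VariantSite], policy: FilterPolicy) -> FilterReport:
    """Apply a filter policy; removed sites record the failing flags.

    ``qual-contamination``: QUAL threshold only.  ``phasing-heuristics``:
    QUAL threshold plus removal of het calls flagged ``bad-phasing`` or
    ``strand-bias``; requires phasing metrics on het sites.
    """
    if policy.name == POLICY_PHASING:
        has_het = any(s.genotype is Genotype.HET for s in sites)
        if has_het and not any(s.pe is not None for s in sites):
            raise ValueError(
                "phasing-heuristics policy requires phasing results (PE) on het sites"
            )
    kept: list[VariantSite] = []
    removed: list[VariantSite] = []
    removal_counts: dict[str, int] = {}
    for s in sites:
        failing: list[str] = []
        if s.qual < policy.qual_threshold:
            failing.append("low-qual")
        if policy.name == POLICY_PHASING and s.genotype is Genotype.HET:
            if "bad-phasing" in s.annotations and "bad-phasing" in policy.enabled_flags:
                failing.append("bad-phasing")
            if "strand-bias" in s.annotations and "strand-bias" in policy.enabled_flags:
                failing.append("strand-bias")
        if failing:
            s.filter_status = failing
            removed.append(s)
            for f in failing:
                removal_counts[f] = removal_counts.get(f, 0) + 1
        else:
            s.filter_status = []
            kept.append(s)
    return FilterReport(kept=kept, removed=removed, removal_counts=removal_counts)
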