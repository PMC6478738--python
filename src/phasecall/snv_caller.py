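"""Frequency-based diploid SNV calling with contamination-adjusted
expected allele fractions.

Genotype likelihoods are binomial on ref/alt counts with alt-read
probabilities: hom-ref ``e`` (base error), het ``1 - c_het``, hom-alt
``1 - c_hom`` (default interpretation of the second contamination
parameter; the literal reading is selectable).  A site needs at least
``min_alt_count`` alternate observations before being considered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .formats_io import (
    BASES,
    BASE_TO_CODE,
    AlignmentRecord,
    Genotype,
    PileupCounts,
    VariantSite,
    _full_pileup_arrays,
)

QUAL_CAP = 3000.0

_GENOTYPES = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)


@dataclass
class GenotypeModel:
    """Contamination-aware genotype model.

    ``c_het`` is p(read = ref | genotype het); ``c_hom`` defaults to
    p(reference-consistent read | genotype hom-alt), so the modeled alt
    fraction at hom-alt sites is ``1 - c_hom``.  Setting
    ``hom_literal=True`` switches to the literal reading where ``c_hom``
    is itself p(read = alt | hom-alt).
    """

    c_het: float = 0.7
    c_hom: float = 0.1
    error_rate: float = 0.05
    min_alt_count: int = 5
    max_alt_alleles: int = 4
    hom_literal: bool = False

    def __post_init__(self) -> None:
        for name in ("c_het", "c_hom", "error_rate"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.min_alt_count < 1:
            raise ValueError("min_alt_count must be >= 1")

    @property
    def alt_probs(self) -> np.ndarray:
        """Alt-read probability per genotype (hom-ref, het, hom-alt)."""
        p_hom_alt = self.c_hom if self.hom_literal else 1.0 - self.c_hom
        return np.array([self.error_rate, 1.0 - self.c_het, p_hom_alt])


def genotype_likelihoods(counts: PileupCounts, model: GenotypeModel) -> np.ndarray | None:
    """Binomial log-likelihood of n_alt out of (n_ref + n_alt) per genotype.

    Returns ``None`` (no-call sentinel) when there is no ref/alt evidence.
    """
    n = counts.n_ref + counts.n_alt
    if n == 0:
        return None
    return binom.logpmf(counts.n_alt, n, model.alt_probs)


def _qual_from_loglik(loglik: np.ndarray) -> float:
    """Phred-scaled P(hom-ref | data) under a flat genotype prior."""
    log_post_hom_ref = loglik[0] - logsumexp(loglik)
    qual = -10.0 / np.log(10.0) * log_post_hom_ref
    return float(min(qual, QUAL_CAP))


def call_site(
    counts: PileupCounts,
    model: GenotypeModel,
    chrom: str = "ref",
    pos: int = 1,
    ref: str = "A",
    alt: str = "C",
) -> VariantSite | None:
    """Call one site; returns ``None`` below the alt-count floor or when
    the maximum-likelihood genotype is hom-ref."""
    if counts.n_alt < model.min_alt_count:
        return None
    loglik = genotype_likelihoods(counts, model)
    if loglik is None:
        return None
    genotype = _GENOTYPES[int(np.argmax(loglik))]
    if genotype is Genotype.HOM_REF:
        return None
    site = VariantSite(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=_qual_from_loglik(loglik),
        genotype=genotype,
    )
    site.info["counts"] = counts
    return site


def call_variants(
    alignments: list[AlignmentRecord],
    reference: str,
    model: GenotypeModel | None = None,
    chrom: str = "ref",
) -> list[VariantSite]:
    """Scan every reference position and call SNVs.

    The best alternate allele is the most frequent non-reference base;
    "other" bases contribute to depth for the alt-count floor but never
    to ``n_alt``.  Vectorized over the genome.
    """
    if model is None:
        model = GenotypeModel()
    L = len(reference)
    base_counts, del_counts = _full_pileup_arrays(alignments, L)
    totals = base_counts.sum(axis=2)  # (L+1, 4)
    ref_codes = np.frombuffer(reference.encode(), dtype=np.uint8)
    code_map = np.full(256, -1, dtype=np.int64)
    for b, c in BASE_TO_CODE.items():
        code_map[ord(b)] = c
    ref_idx = np.concatenate([[0], code_map[ref_codes]])  # 1-based alignment
    pos_idx = np.arange(L + 1)
    masked = totals.copy()
    valid_ref = ref_idx >= 0
    masked[pos_idx[valid_ref], ref_idx[valid_ref]] = -1
    alt_idx = masked.argmax(axis=1)
    n_alt = np.where(valid_ref, totals[pos_idx, alt_idx], 0)
    candidates = np.nonzero((n_alt >= model.min_alt_count) & valid_ref)[0]
    candidates = candidates[candidates >= 1]

    calls: list[VariantSite] = []
    if candidates.size == 0:
        return calls
    n_ref_c = totals[candidates, ref_idx[candidates]]
    n_alt_c = n_alt[candidates]
    n_c = n_ref_c + n_alt_c
    alt_p = model.alt_probs
    loglik = np.stack(
        [binom.logpmf(n_alt_c, n_c, p) for p in alt_p], axis=1
    )  # (n_cand, 3)
    gt_idx = loglik.argmax(axis=1)
    log_post_hr = loglik[:, 0] - logsumexp(loglik, axis=1)
    quals = np.minimum(-10.0 / np.log(10.0) * log_post_hr, QUAL_CAP)
    for i, p in enumerate(candidates):
        if gt_idx[i] == 0:
            continue
        a_idx = alt_idx[p]
        cnt = PileupCounts(
            ref_fwd=int(base_counts[p, ref_idx[p], 0]),
            ref_rev=int(base_counts[p, ref_idx[p], 1]),
            alt_fwd=int(base_counts[p, a_idx, 0]),
            alt_rev=int(base_counts[p, a_idx, 1]),
            other_fwd=int(base_counts[p, :, 0].sum() - base_counts[p, ref_idx[p], 0] - base_counts[p, a_idx, 0]),
            other_rev=int(base_counts[p, :, 1].sum() - base_counts[p, ref_idx[p], 1] - base_counts[p, a_idx, 1]),
            del_fwd=int(del_counts[p, 0]),
            del_rev=int(del_counts[p, 1]),
        )
        site = VariantSite(
            chrom=chrom,
            pos=int(p),
            ref=BASES[ref_idx[p]],
            alt=BASES[a_idx],
            qual=float(quals[i]),
            genotype=_GENOTYPES[int(gt_idx[i])],
        )
        site.info["counts"] = cnt
        calls.append(site)
    return calls
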