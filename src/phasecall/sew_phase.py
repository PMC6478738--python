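"""Probabilistic read-backed phasing of heterozygous SNVs.

An individual carries two haplotypes (no recombination within a phase
set).  Each read originates from one of them with prior 0.5; at every
het site a per-haplotype emission probability ``theta[t, h]`` gives the
chance that a read from haplotype ``h`` carries the alternate base.
Base-call noise enters through the phred-derived probability ``psi``.
Reads and emissions are fitted jointly by EM; the latent true base at
each observation is marginalized analytically.

Derived per-site metrics: phase entropy
``PE = -log10(theta1 * theta2 * (1-theta1) * (1-theta2))`` (high for
cleanly separated real hets, low for phase-inconsistent false calls) and
per-haplotype forward-strand counts SB1/SB2 after hard read assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import binomtest

from .formats_io import AlignmentRecord, VariantSite

logger = logging.getLogger(__name__)

LOG_HALF = float(np.log(0.5))


@dataclass
class ReadObservation:
    """One read's evidence at the het sites it spans.

    ``site_indices`` index into the global het-site list (strictly
    increasing); ``alleles`` are 0 (ref) / 1 (alt) — "other" and deleted
    bases are excluded before construction.
    """

    index: int
    strand: str
    site_indices: np.ndarray
    alleles: np.ndarray
    quals: np.ndarray
    posterior: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.site_indices = np.asarray(self.site_indices, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.quals = np.asarray(self.quals, dtype=np.float64)
        if self.site_indices.size == 0:
            raise ValueError("a ReadObservation must span at least one het site")
        if not np.all(np.diff(self.site_indices) > 0):
            raise ValueError("site indices must be strictly increasing")
        if np.any(self.quals < 0):
            raise ValueError("negative base quality")

    @property
    def n_sites(self) -> int:
        return int(self.site_indices.size)


@dataclass
class EMConfig:
    tol: float = 1e-4
    max_iter: int = 200
    eps_theta: float = 1e-6
    seed: int = 0
    n_restarts: int = 5  # random-restart EM; best observed loglik wins


@dataclass
class EmissionMatrix:
    """Fitted per-site, per-haplotype alt emission probabilities."""

    theta: np.ndarray  # (n_sites, 2), clamped to [eps, 1-eps]
    estimable: np.ndarray  # (n_sites,) bool; False where no read covers the site

    @property
    def pe(self) -> np.ndarray:
        return phase_entropy(self.theta[:, 0], self.theta[:, 1])


@dataclass
class PhaseSet:
    """Het sites transitively connected by multi-site reads."""

    identifier: int
    site_indices: list[int]
    emissions: EmissionMatrix | None = None


@dataclass
class EMResult:
    emissions: EmissionMatrix
    posteriors: np.ndarray  # (n_reads, 2)
    loglik_trace: list[float]
    n_iter: int


def psi(s: int, g: int, b: float) -> float:
    """P(observed allele ``s`` | true allele ``g``) from a phred quality.

    Biallelic convention: a mismatch has probability ``eps = 10^(-b/10)``
    in full (not ``eps/3``); "other" bases never reach this function.
    """
    if b < 0:
        raise ValueError("phred quality must be >= 0")
    eps = 10.0 ** (-b / 10.0)
    return 1.0 - eps if s == g else eps


def _obs_arrays(reads: list[ReadObservation]):
    """Flatten observations: (read index, site index, psi(s,1,b))."""
    obs_read = np.concatenate(
        [np.full(r.n_sites, i, dtype=np.int64) for i, r in enumerate(reads)]
    )
    obs_site = np.concatenate([r.site_indices for r in reads])
    alleles = np.concatenate([r.alleles for r in reads]).astype(np.float64)
    quals = np.concatenate([r.quals for r in reads])
    eps = 10.0 ** (-quals / 10.0)
    # psi(s, g=1, b): 1-eps when s==1, else eps; psi(s,0,b) == 1 - psi(s,1,b)
    psi1 = np.where(alleles == 1.0, 1.0 - eps, eps)
    return obs_read, obs_site, psi1


def read_hap_likelihood(read: ReadObservation, h: int, theta: np.ndarray) -> float:
    """P(read's observed alleles | haplotype ``h``, theta), Eq.-3 mixture."""
    if read.n_sites == 0:
        raise ValueError("read spans zero usable sites")
    th = theta[read.site_indices, h]
    eps = 10.0 ** (-read.quals / 10.0)
    psi1 = np.where(read.alleles == 1, 1.0 - eps, eps)
    psi0 = 1.0 - psi1
    return float(np.prod(psi1 * th + psi0 * (1.0 - th)))


def complete_data_loglik(
    reads: list[ReadObservation], hap_assignments: np.ndarray, theta: np.ndarray
) -> float:
    """Log P(observations, hard haplotype assignments | theta).

    The 0.5 haplotype prior is applied once per read.
    """
    total = 0.0
    for read, h in zip(reads, np.asarray(hap_assignments)):
        total += LOG_HALF + np.log(read_hap_likelihood(read, int(h), theta))
    return float(total)


def _estep(obs_read, obs_site, psi1, theta, n_reads):
    """Posterior over haplotypes per read plus observed-data loglik."""
    th = theta[obs_site, :]  # (n_obs, 2)
    mix = psi1[:, None] * th + (1.0 - psi1)[:, None] * (1.0 - th)
    log_mix = np.log(mix)
    ll = np.zeros((n_reads, 2))
    for h in (0, 1):
        ll[:, h] = np.bincount(obs_read, weights=log_mix[:, h], minlength=n_reads)
    joint = LOG_HALF + ll
    norm = logsumexp(joint, axis=1)
    post = np.exp(joint - norm[:, None])
    return post, float(np.sum(norm))


def _mstep(obs_read, obs_site, psi1, theta, post, n_sites, eps_theta):
    th = theta[obs_site, :]
    num_g = psi1[:, None] * th
    gamma1 = num_g / (num_g + (1.0 - psi1)[:, None] * (1.0 - th))
    new = np.full((n_sites, 2), 0.5)
    denom = np.zeros((n_sites, 2))
    for h in (0, 1):
        w = post[obs_read, h]
        num = np.bincount(obs_site, weights=w * gamma1[:, h], minlength=n_sites)
        den = np.bincount(obs_site, weights=w, minlength=n_sites)
        denom[:, h] = den
        ok = den > 0
        new[ok, h] = num[ok] / den[ok]
    estimable = (denom.sum(axis=1) > 0)
    return np.clip(new, eps_theta, 1.0 - eps_theta), estimable


def _init_theta(n_sites: int, rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0.2, 0.8, size=(n_sites, 2))
    # anchor the first site to break haplotype-label symmetry deterministically
    theta[0, 0] = 0.9
    theta[0, 1] = 0.1
    return theta


def em_fit(
    reads: list[ReadObservation], n_sites: int, config: EMConfig | None = None
) -> EMResult:
    """Fit emissions and read posteriors by EM.

    E-step: read-haplotype posteriors under the 0.5 prior.  M-step:
    posterior-weighted, quality-weighted alt fraction per (site,
    haplotype).  Stops when the observed-data log-likelihood improves by
    less than ``tol``; the trace is monotone non-decreasing.
    """
    if config is None:
        config = EMConfig()
    if n_sites == 0 or not reads:
        raise ValueError("em_fit needs at least one site and one read")
    obs_read, obs_site, psi1 = _obs_arrays(reads)
    if obs_site.max() >= n_sites:
        raise ValueError("observation references a site index >= n_sites")
    rng = np.random.default_rng(config.seed)
    n_reads = len(reads)

    def _run(theta_init: np.ndarray) -> EMResult:
        theta = theta_init
        trace: list[float] = []
        estimable = np.ones(n_sites, dtype=bool)
        for _ in range(config.max_iter):
            post, loglik = _estep(obs_read, obs_site, psi1, theta, n_reads)
            trace.append(loglik)
            theta, estimable = _mstep(
                obs_read, obs_site, psi1, theta, post, n_sites, config.eps_theta
            )
            if len(trace) > 1 and trace[-1] - trace[-2] < config.tol:
                break
        post, loglik = _estep(obs_read, obs_site, psi1, theta, n_reads)
        trace.append(loglik)
        return EMResult(
            emissions=EmissionMatrix(theta=theta, estimable=estimable),
            posteriors=post,
            loglik_trace=trace,
            n_iter=len(trace) - 1,
        )

    best: EMResult | None = None
    for _ in range(max(1, config.n_restarts)):
        result = _run(_init_theta(n_sites, rng))
        if best is None or result.loglik_trace[-1] > best.loglik_trace[-1]:
            best = result
    # classification-EM polish as one adaptive restart: refine the hard
    # assignment greedily, then restart soft EM from the refined theta
    assign = np.where(best.posteriors[:, 0] >= best.posteriors[:, 1], 0, 1)
    theta = best.emissions.theta
    for _ in range(50):
        one_hot = np.zeros((n_reads, 2))
        one_hot[np.arange(n_reads), assign] = 1.0
        theta, _ = _mstep(
            obs_read, obs_site, psi1, theta, one_hot, n_sites, config.eps_theta
        )
        post_h, _ = _estep(obs_read, obs_site, psi1, theta, n_reads)
        new_assign = np.where(post_h[:, 0] >= post_h[:, 1], 0, 1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    polished = _run(theta)
    if polished.loglik_trace[-1] > best.loglik_trace[-1] + 1e-12:
        best = polished
    for read, p in zip(reads, best.posteriors):
        read.posterior = p
    if not best.emissions.estimable.all():
        logger.warning(
            "%d site(s) covered by no read; theta flagged unestimable",
            int((~best.emissions.estimable).sum()),
        )
    return best


def assignment_loglik(
    reads: list[ReadObservation], assignment: np.ndarray, n_sites: int,
    eps_theta: float = 1e-6,
) -> float:
    """Complete-data log-likelihood of a hard assignment with theta
    re-optimized per (site, haplotype).

    The per-parameter objective is a sum of logs of functions linear in
    theta, hence concave; a bounded scalar optimizer finds the optimum.
    Used as the shared evaluation for EM-vs-exhaustive comparisons.
    """
    assignment = np.asarray(assignment)
    obs_read, obs_site, psi1 = _obs_arrays(reads)
    obs_hap = assignment[obs_read]
    total = len(reads) * LOG_HALF
    for h in (0, 1):
        sel = obs_hap == h
        for t in np.unique(obs_site[sel]):
            p1 = psi1[sel & (obs_site == t)]

            def neg(theta, p1=p1):
                return -np.sum(np.log(p1 * theta + (1.0 - p1) * (1.0 - theta)))

            res = minimize_scalar(
                neg, bounds=(eps_theta, 1.0 - eps_theta), method="bounded",
                options={"xatol": 1e-12},
            )
            total -= res.fun
    return float(total)


def phase_entropy(theta1, theta2, eps_theta: float = 1e-6):
    """PE = -log10(theta1 * theta2 * (1-theta1) * (1-theta2))."""
    t1 = np.clip(np.asarray(theta1, dtype=float), eps_theta, 1.0 - eps_theta)
    t2 = np.clip(np.asarray(theta2, dtype=float), eps_theta, 1.0 - eps_theta)
    out = -np.log10(t1 * t2 * (1.0 - t1) * (1.0 - t2))
    return float(out) if out.ndim == 0 else out


def hard_assignments(reads: list[ReadObservation]) -> np.ndarray:
    """Arg-max haplotype per read; posterior ties go to haplotype 1."""
    post = np.vstack([r.posterior for r in reads])
    return np.where(post[:, 0] >= post[:, 1], 0, 1)


@dataclass
class StrandBiasCounts:
    sb1: int  # forward-strand reads assigned to haplotype 1
    sb2: int
    n_hap1: int
    n_hap2: int

    def binomial_pvalues(self) -> tuple[float, float]:
        """Two-sided binomial(0.5) strand-balance p-value per haplotype."""
        p1 = binomtest(self.sb1, self.n_hap1, 0.5).pvalue if self.n_hap1 else 1.0
        p2 = binomtest(self.sb2, self.n_hap2, 0.5).pvalue if self.n_hap2 else 1.0
        return p1, p2


def haplotype_strand_bias(reads: list[ReadObservation]) -> StrandBiasCounts:
    """Forward-strand counts per haplotype after hard assignment."""
    assign = hard_assignments(reads)
    fwd = np.array([r.strand == "+" for r in reads])
    return StrandBiasCounts(
        sb1=int(np.sum(fwd & (assign == 0))),
        sb2=int(np.sum(fwd & (assign == 1))),
        n_hap1=int(np.sum(assign == 0)),
        n_hap2=int(np.sum(assign == 1)),
    )


def build_phase_sets(reads: list[ReadObservation], n_sites: int) -> list[PhaseSet]:
    """Connected components of sites co-spanned by reads; singletons too."""
    parent = list(range(n_sites))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for r in reads:
        first = int(r.site_indices[0])
        for t in r.site_indices[1:]:
            union(first, int(t))
    groups: dict[int, list[int]] = {}
    for t in range(n_sites):
        groups.setdefault(find(t), []).append(t)
    return [
        PhaseSet(identifier=root, site_indices=sorted(members))
        for root, members in sorted(groups.items())
    ]


def observations_from_alignments(
    alignments: list[AlignmentRecord], sites: list[VariantSite]
) -> list[ReadObservation]:
    """Extract ref/alt observations at het sites from alignments.

    Bases matching neither allele and in-read deletions are excluded;
    reads left with no usable observation are dropped (count logged).
    """
    positions = np.array([s.pos for s in sites], dtype=np.int64)
    order = np.argsort(positions)
    positions = positions[order]
    refs = np.frombuffer("".join(sites[i].ref for i in order).encode(), dtype=np.uint8)
    alts = np.frombuffer("".join(sites[i].alt for i in order).encode(), dtype=np.uint8)
    out: list[ReadObservation] = []
    n_dropped = 0
    for idx, rec in enumerate(alignments):
        ref_pos, read_idx, _, _ = rec.expand()
        if ref_pos.size == 0:
            n_dropped += 1
            continue
        lo, hi = np.searchsorted(positions, [ref_pos[0], ref_pos[-1] + 1])
        cand = np.arange(lo, hi)
        if cand.size == 0:
            n_dropped += 1
            continue
        hit = np.searchsorted(ref_pos, positions[cand])
        present = ref_pos[np.minimum(hit, ref_pos.size - 1)] == positions[cand]
        cand = cand[present]
        hit = hit[present]
        if cand.size == 0:
            n_dropped += 1
            continue
        seq = np.frombuffer(rec.seq.encode(), dtype=np.uint8)
        bases = seq[read_idx[hit]]
        is_ref = bases == refs[cand]
        is_alt = bases == alts[cand]
        usable = is_ref | is_alt
        if not usable.any():
            n_dropped += 1
            continue
        out.append(
            ReadObservation(
                index=idx,
                strand=rec.strand,
                site_indices=order[cand[usable]],
                alleles=is_alt[usable].astype(np.int8),
                quals=rec.quals[read_idx[hit]][usable].astype(np.float64),
            )
        )
    if n_dropped:
        logger.info("dropped %d read(s) with no usable het-site observation", n_dropped)
    # site indices must refer to the caller's ordering; re-sort if needed
    for r in out:
        srt = np.argsort(r.site_indices)
        r.site_indices = r.site_indices[srt]
        r.alleles = r.alleles[srt]
        r.quals = r.quals[srt]
    return out


@dataclass
class PhasingResult:
    """Per-site phasing output over all phase sets."""

    theta: np.ndarray  # (n_sites, 2)
    pe: np.ndarray  # (n_sites,)
    phase_set_of_site: np.ndarray  # (n_sites,) id, or -1 if uncovered
    hap_of_alt: np.ndarray  # (n_sites,) 1 or 2
    strand_bias: dict[int, StrandBiasCounts]
    phase_sets: list[PhaseSet]
    reads: list[ReadObservation]
    estimable: np.ndarray


def write_metrics_tsv(
    result: "PhasingResult", sites: list[VariantSite], path
) -> None:
    """Per-site phasing metrics table (TSV)."""
    import pandas as pd

    n_by_hap = {}
    for ps_id, sb in result.strand_bias.items():
        n_by_hap[ps_id] = (sb.n_hap1, sb.n_hap2, sb.sb1, sb.sb2)
    rows = []
    for i, s in enumerate(sites):
        ps = int(result.phase_set_of_site[i])
        n1, n2, sb1, sb2 = n_by_hap.get(ps, (0, 0, 0, 0))
        rows.append(
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "phase_set": ps,
                "theta_1": round(float(result.theta[i, 0]), 6),
                "theta_2": round(float(result.theta[i, 1]), 6),
                "PE": round(float(result.pe[i]), 4),
                "SB1": sb1,
                "SB2": sb2,
                "n_reads_hap1": n1,
                "n_reads_hap2": n2,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_phasing(
    reads: list[ReadObservation],
    n_sites: int,
    config: EMConfig | None = None,
    prune_pe_threshold: float | None = None,
) -> PhasingResult:
    """EM per phase set; optional one-round pruning of low-PE sites.

    With ``prune_pe_threshold`` set, sites whose PE falls below the
    threshold after the first fit are removed and the set refitted once
    (the pruned sites keep their first-round metrics).
    """
    if config is None:
        config = EMConfig()
    phase_sets = build_phase_sets(reads, n_sites)
    theta = np.full((n_sites, 2), 0.5)
    pe = np.zeros(n_sites)
    ps_of_site = np.full(n_sites, -1, dtype=np.int64)
    hap_of_alt = np.ones(n_sites, dtype=np.int64)
    estimable = np.zeros(n_sites, dtype=bool)
    sb: dict[int, StrandBiasCounts] = {}
    reads_of_set: dict[int, list[ReadObservation]] = {ps.identifier: [] for ps in phase_sets}
    site_to_set = {}
    for ps in phase_sets:
        for t in ps.site_indices:
            site_to_set[t] = ps.identifier
    for r in reads:
        reads_of_set[site_to_set[int(r.site_indices[0])]].append(r)
    for k, ps in enumerate(phase_sets):
        sub_reads_all = reads_of_set[ps.identifier]
        if not sub_reads_all:
            continue
        local = {t: i for i, t in enumerate(ps.site_indices)}
        sub_reads = [
            ReadObservation(
                index=r.index,
                strand=r.strand,
                site_indices=np.array([local[int(t)] for t in r.site_indices]),
                alleles=r.alleles,
                quals=r.quals,
            )
            for r in sub_reads_all
        ]
        sub_cfg = EMConfig(
            tol=config.tol,
            max_iter=config.max_iter,
            eps_theta=config.eps_theta,
            seed=config.seed + k,
            n_restarts=config.n_restarts,
        )
        fit = em_fit(sub_reads, len(ps.site_indices), sub_cfg)
        if prune_pe_threshold is not None:
            site_pe = fit.emissions.pe
            keep = site_pe >= prune_pe_threshold
            if (~keep).any() and keep.any():
                kept_global = [t for t, k_ in zip(ps.site_indices, keep) if k_]
                remap = {local[t]: i for i, t in enumerate(kept_global)}
                refit_reads = []
                for r in sub_reads:
                    mask = keep[r.site_indices]
                    if mask.any():
                        refit_reads.append(
                            ReadObservation(
                                index=r.index,
                                strand=r.strand,
                                site_indices=np.array(
                                    [remap[int(t)] for t in r.site_indices[mask]]
                                ),
                                alleles=r.alleles[mask],
                                quals=r.quals[mask],
                            )
                        )
                if refit_reads:
                    refit = em_fit(refit_reads, len(kept_global), sub_cfg)
                    for i, t in enumerate(kept_global):
                        fit.emissions.theta[local[t]] = refit.emissions.theta[i]
                        fit.emissions.estimable[local[t]] = refit.emissions.estimable[i]
                    # carry refitted posteriors back onto the original reads
                    by_index = {r.index: r for r in sub_reads}
                    for r in refit_reads:
                        by_index[r.index].posterior = r.posterior
        idx = np.array(ps.site_indices)
        theta[idx] = fit.emissions.theta
        pe[idx] = phase_entropy(
            fit.emissions.theta[:, 0], fit.emissions.theta[:, 1], config.eps_theta
        )
        estimable[idx] = fit.emissions.estimable
        ps_of_site[idx] = ps.identifier
        hap_of_alt[idx] = np.where(
            fit.emissions.theta[:, 0] >= fit.emissions.theta[:, 1], 1, 2
        )
        ps.emissions = fit.emissions
        sb[ps.identifier] = haplotype_strand_bias(sub_reads)
        for orig, sub in zip(sub_reads_all, sub_reads):
            orig.posterior = sub.posterior
    return PhasingResult(
        theta=theta,
        pe=pe,
        phase_set_of_site=ps_of_site,
        hap_of_alt=hap_of_alt,
        strand_bias=sb,
        phase_sets=phase_sets,
        reads=reads,
        estimable=estimable,
    )
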