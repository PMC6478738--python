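"""Evaluation arithmetic: alignment error rates, call classification
with genotype-mismatch double counting, switch error rate, proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .formats_io import AlignmentRecord, VariantSite


@dataclass
class ErrorRates:
    """Per-alignment error decomposition.

    e_sub: mismatches / aligned (non-gap) base pairs.
    e_del: deleted reference bases / aligned reference length.
    e_ins: inserted read bases / aligned read length.
    p_id = 100 * (1 - e_sub).
    """

    e_sub: float
    e_del: float
    e_ins: float
    n_aligned: int

    @property
    def p_id(self) -> float:
        return 100.0 * (1.0 - self.e_sub)


def alignment_error_rates(record: AlignmentRecord, reference: str) -> ErrorRates | None:
    """Error rates of one alignment against the reference.

    Returns ``None`` when the alignment has zero aligned bases.
    """
    ref_pos, read_idx, del_pos, n_ins = record.expand()
    n_aligned = int(ref_pos.size)
    if n_aligned == 0:
        return None
    ref_arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    if ref_pos[-1] > ref_arr.size:
        raise IndexError(f"alignment {record.name} extends beyond reference")
    read_arr = np.frombuffer(record.seq.encode(), dtype=np.uint8)
    mismatches = int(np.sum(read_arr[read_idx] != ref_arr[ref_pos - 1]))
    n_del = int(del_pos.size)
    return ErrorRates(
        e_sub=mismatches / n_aligned,
        e_del=n_del / (n_aligned + n_del),
        e_ins=n_ins / (n_aligned + n_ins),
        n_aligned=n_aligned,
    )


def aggregate_error_rates(rates: list[ErrorRates]) -> ErrorRates:
    """Aligned-length-weighted mean of per-alignment rates."""
    rates = [r for r in rates if r is not None]
    if not rates:
        raise ValueError("no alignments with aligned bases")
    w = np.array([r.n_aligned for r in rates], dtype=float)
    w = w / w.sum()
    return ErrorRates(
        e_sub=float(np.sum(w * [r.e_sub for r in rates])),
        e_del=float(np.sum(w * [r.e_del for r in rates])),
        e_ins=float(np.sum(w * [r.e_ins for r in rates])),
        n_aligned=int(sum(r.n_aligned for r in rates)),
    )


@dataclass
class CallClassification:
    tp: int
    fp: int
    fn: int

    @property
    def fdr(self) -> float:
        """FP / (TP + FP); 0 when no calls were made."""
        return self.fp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def fnr(self) -> float:
        return self.fn / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def precision(self) -> float:
        return 1.0 - self.fdr

    @property
    def recall(self) -> float:
        return 1.0 - self.fnr

    @property
    def f1(self) -> float:
        return f1_from_rates(self.fdr, self.fnr)


def _in_region(site: VariantSite, region) -> bool:
    if region is None:
        return True
    return any(
        site.chrom == chrom and start0 < site.pos <= end
        for chrom, start0, end in region
    )


def classify_calls(
    calls: list[VariantSite],
    truth: list[VariantSite],
    region: list[tuple[str, int, int]] | None = None,
) -> CallClassification:
    """TP/FP/FN classification at position + genotype resolution.

    A call at a truth position with a different genotype (or allele)
    counts both as a false positive and a false negative.
    """
    calls = [c for c in calls if _in_region(c, region)]
    truth = [t for t in truth if _in_region(t, region)]
    for name, group in (("calls", calls), ("truth", truth)):
        keys = [(s.chrom, s.pos) for s in group]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicated positions in {name}")
    truth_by_pos = {(t.chrom, t.pos): t for t in truth}
    tp = fp = 0
    for c in calls:
        t = truth_by_pos.get((c.chrom, c.pos))
        if t is not None and t.alt == c.alt and t.genotype == c.genotype:
            tp += 1
        else:
            fp += 1
    fn = len(truth) - tp
    return CallClassification(tp=tp, fp=fp, fn=fn)


def f1_from_rates(fdr: float, fnr: float) -> float:
    """F1 = 2 / (1/(1-FDR) + 1/(1-FNR)), harmonic mean of precision and
    recall; 0 by continuity when either rate is 1."""
    if not (0.0 <= fdr <= 1.0 and 0.0 <= fnr <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    if fdr == 1.0 or fnr == 1.0:
        return 0.0
    return 2.0 / (1.0 / (1.0 - fdr) + 1.0 / (1.0 - fnr))


@dataclass
class SwitchErrorResult:
    rate: float  # NaN when no evaluable pairs
    n_switches: int
    n_pairs: int


def switch_error_rate(
    phased_calls: list[VariantSite],
    phased_truth: list[VariantSite],
    mode: str = "all",
    reads: list[AlignmentRecord] | None = None,
) -> SwitchErrorResult:
    """Fraction of adjacent shared-het-site pairs with discordant
    relative phase.

    Pairs are formed within call-side phase sets from het sites phased in
    both inputs.  ``mode='read-spanned'`` keeps only pairs co-spanned by
    at least one read.  Invariant to global haplotype relabeling per
    phase set.
    """
    if mode not in ("all", "read-spanned"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "read-spanned" and reads is None:
        raise ValueError("read-spanned mode requires reads")

    def _phased_hets(sites):
        return {
            (s.chrom, s.pos): s
            for s in sites
            if s.hap_of_alt is not None and s.phase_set is not None
        }

    calls = _phased_hets(phased_calls)
    truth = _phased_hets(phased_truth)
    shared = sorted(set(calls) & set(truth))
    n_pairs = 0
    n_switch = 0
    for (chrom_a, pos_a), (chrom_b, pos_b) in zip(shared, shared[1:]):
        if chrom_a != chrom_b:
            continue
        ca, cb = calls[(chrom_a, pos_a)], calls[(chrom_b, pos_b)]
        ta, tb = truth[(chrom_a, pos_a)], truth[(chrom_b, pos_b)]
        if ca.phase_set != cb.phase_set or ta.phase_set != tb.phase_set:
            continue
        if mode == "read-spanned" and not any(
            r.ref_name == chrom_a and r.pos <= pos_a and r.ref_end >= pos_b
            for r in reads
        ):
            continue
        n_pairs += 1
        call_same = ca.hap_of_alt == cb.hap_of_alt
        truth_same = ta.hap_of_alt == tb.hap_of_alt
        if call_same != truth_same:
            n_switch += 1
    rate = n_switch / n_pairs if n_pairs else math.nan
    return SwitchErrorResult(rate=rate, n_switches=n_switch, n_pairs=n_pairs)


def proportion(numerator: int, denominator: int, decimals: int | None = None) -> float:
    """100 * numerator / denominator, optionally rounded for display."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = 100.0 * numerator / denominator
    return round(pct, decimals) if decimals is not None else pct
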