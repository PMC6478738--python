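"""Synthetic diploid genome and noisy long-read simulation.

Produces a random reference, two haplotype sequences carrying phased
truth SNVs, and reads with substitution/insertion/deletion errors whose
per-read rate is drawn from a truncated normal accuracy distribution and
whose composition follows a configurable difference ratio.  Reads come
with their exact generating alignment (CIGAR), so no aligner is needed
downstream.  Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import BASES, AlignmentRecord, Genotype, VariantSite

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class SimulationConfig:
    ref_length: int = 100_000
    het_density: float = 0.001
    hom_density: float = 0.0005
    read_length_mean: float = 6373.0
    read_length_sigma: float = 0.25  # log-normal shape
    accuracy_mean: float = 0.795
    accuracy_sd: float = 0.20
    accuracy_min: float = 0.40
    difference_ratio: tuple[float, float, float] = (60.0, 35.0, 5.0)  # sub:ins:del
    depth_per_haplotype: float = 20.0
    seed: int = 0
    chrom: str = "ref"

    def __post_init__(self) -> None:
        if any(x <= 0 for x in self.difference_ratio):
            raise ValueError("difference ratio components must be positive")
        if not 0.0 < self.accuracy_min <= 1.0:
            raise ValueError("accuracy_min must be in (0,1]")
        for d in (self.het_density, self.hom_density):
            if not 0.0 <= d < 1.0:
                raise ValueError("densities must be in [0,1)")

    @property
    def error_fractions(self) -> np.ndarray:
        r = np.asarray(self.difference_ratio, dtype=float)
        return r / r.sum()


@dataclass
class DiploidTruth:
    reference: str
    haplotypes: tuple[str, str]
    variants: list[VariantSite] = field(default_factory=list)

    @property
    def het_sites(self) -> list[VariantSite]:
        return [v for v in self.variants if v.genotype is Genotype.HET]


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def simulate_diploid(config: SimulationConfig) -> DiploidTruth:
    """Random reference plus two haplotypes with phased truth SNVs.

    Het variants land on a random haplotype; hom-alt variants on both.
    Variant positions keep at least one reference base between them.
    """
    rng = np.random.default_rng(config.seed)
    ref = _random_sequence(rng, config.ref_length)
    n_het = rng.binomial(config.ref_length, config.het_density)
    n_hom = rng.binomial(config.ref_length, config.hom_density)
    n_total = n_het + n_hom
    positions = np.empty(0, dtype=np.int64)
    while positions.size < n_total:
        need = n_total - positions.size
        draw = rng.choice(config.ref_length, size=need * 2 + 8, replace=False)
        pool = np.sort(np.unique(np.concatenate([positions, draw])))
        # enforce >= 2 bp separation greedily
        keep = [int(pool[0])] if pool.size else []
        for p in pool[1:]:
            if p - keep[-1] >= 2:
                keep.append(int(p))
        positions = np.array(keep[: n_total], dtype=np.int64)
        if positions.size < n_total and pool.size >= config.ref_length // 2:
            break  # reference saturated; accept fewer variants
    rng.shuffle(positions)
    het_pos = np.sort(positions[:n_het])
    hom_pos = np.sort(positions[n_het:])

    hap1 = ref.copy()
    hap2 = ref.copy()
    variants: list[VariantSite] = []
    for pos0 in het_pos:
        ref_code = int(ref[pos0])
        alt_code = (ref_code + int(rng.integers(1, 4))) % 4
        hap = int(rng.integers(1, 3))
        (hap1 if hap == 1 else hap2)[pos0] = alt_code
        variants.append(
            VariantSite(
                chrom=config.chrom,
                pos=int(pos0) + 1,
                ref=BASES[ref_code],
                alt=BASES[alt_code],
                qual=100.0,
                genotype=Genotype.HET,
                phase_set=1,
                hap_of_alt=hap,
            )
        )
    for pos0 in hom_pos:
        ref_code = int(ref[pos0])
        alt_code = (ref_code + int(rng.integers(1, 4))) % 4
        hap1[pos0] = alt_code
        hap2[pos0] = alt_code
        variants.append(
            VariantSite(
                chrom=config.chrom,
                pos=int(pos0) + 1,
                ref=BASES[ref_code],
                alt=BASES[alt_code],
                qual=100.0,
                genotype=Genotype.HOM_ALT,
            )
        )
    variants.sort(key=lambda v: v.pos)
    return DiploidTruth(
        reference=_codes_to_str(ref),
        haplotypes=(_codes_to_str(hap1), _codes_to_str(hap2)),
        variants=variants,
    )


def _draw_accuracy(rng: np.random.Generator, config: SimulationConfig) -> float:
    """Truncated-normal accuracy draw on [accuracy_min, 1]."""
    while True:
        a = rng.normal(config.accuracy_mean, config.accuracy_sd)
        if config.accuracy_min <= a <= 1.0:
            return float(a)


def _mutate_read(
    rng: np.random.Generator,
    template: np.ndarray,
    error_rate: float,
    fractions: np.ndarray,
) -> tuple[np.ndarray, list[tuple[str, int]], int]:
    """Apply per-base errors; returns (read codes, CIGAR ops, leading trim).

    Categories per template base: match, substitution (M), insertion of a
    random base after the base (M then 1I), single-base deletion (D).
    """
    n = template.size
    u = rng.random(n)
    p_sub, p_ins, p_del = error_rate * fractions
    cat = np.zeros(n, dtype=np.int8)
    cat[u < p_sub + p_ins + p_del] = 3
    cat[u < p_sub + p_ins] = 2
    cat[u < p_sub] = 1
    out_counts = np.ones(n, dtype=np.int64)
    out_counts[cat == 2] = 2
    out_counts[cat == 3] = 0
    read = np.repeat(template, out_counts)
    starts = np.cumsum(out_counts) - out_counts
    sub_idx = np.nonzero(cat == 1)[0]
    if sub_idx.size:
        shift = rng.integers(1, 4, size=sub_idx.size, dtype=np.int8)
        read[starts[sub_idx]] = (template[sub_idx] + shift) % 4
    ins_idx = np.nonzero(cat == 2)[0]
    if ins_idx.size:
        read[starts[ins_idx] + 1] = rng.integers(0, 4, size=ins_idx.size, dtype=np.int8)
    # run-length encode per-base ops into CIGAR: 0=M, 1=I, 2=D
    ops = np.where(cat == 3, 2, 0).astype(np.int8)
    rep = np.ones(n, dtype=np.int64)
    rep[cat == 2] = 2  # insertion: M for the base, then one I
    per_base = np.repeat(ops, rep)
    if ins_idx.size:
        second = np.cumsum(rep) - 1
        per_base[second[cat == 2]] = 1
    cigar: list[tuple[str, int]] = []
    op_codes = "MID"
    change = np.nonzero(np.diff(per_base) != 0)[0]
    run_starts = np.concatenate([[0], change + 1])
    run_ends = np.concatenate([change, [per_base.size - 1]])
    for s, e in zip(run_starts, run_ends):
        cigar.append((op_codes[per_base[s]], int(e - s + 1)))
    # alignments must not start or end with a deletion
    lead = 0
    if cigar and cigar[0][0] == "D":
        lead = cigar.pop(0)[1]
    if cigar and cigar[-1][0] == "D":
        cigar.pop()
    return read, cigar, lead


def simulate_reads(
    truth: DiploidTruth, config: SimulationConfig
) -> list[AlignmentRecord]:
    """Draw reads from both haplotypes until each reaches its target depth.

    Returns the truth alignments (reference-oriented sequence + exact
    CIGAR); haplotypes carry SNVs only, so haplotype coordinates equal
    reference coordinates.  Base qualities encode the per-read error rate.
    """
    if config.depth_per_haplotype <= 0:
        import warnings

        warnings.warn("depth_per_haplotype is 0; no reads simulated")
        return []
    rng = np.random.default_rng(config.seed + 1)
    fractions = config.error_fractions
    L = len(truth.reference)
    mu = np.log(config.read_length_mean) - config.read_length_sigma**2 / 2.0
    records: list[AlignmentRecord] = []
    counter = 0
    for hap_idx, hap_seq in enumerate(truth.haplotypes, start=1):
        hap_codes = np.frombuffer(hap_seq.encode(), dtype=np.uint8)
        code_of = np.zeros(256, dtype=np.int8)
        for i, b in enumerate(BASES):
            code_of[ord(b)] = i
        hap_codes = code_of[hap_codes]
        target = config.depth_per_haplotype * L
        covered = 0
        while covered < target:
            length = int(np.clip(rng.lognormal(mu, config.read_length_sigma), 200, L))
            # sample over [-len+1, L) and clip so edge coverage stays uniform
            start0 = int(rng.integers(1 - length, L))
            end0 = min(start0 + length, L)
            start0 = max(start0, 0)
            length = end0 - start0
            if length < 50:
                continue
            accuracy = _draw_accuracy(rng, config)
            error_rate = 1.0 - accuracy
            template = hap_codes[start0 : start0 + length]
            read_codes, cigar, lead = _mutate_read(rng, template, error_rate, fractions)
            if not cigar or read_codes.size == 0:
                continue
            start0 += lead
            strand = "+" if rng.random() < 0.5 else "-"
            q = int(np.clip(round(-10.0 * np.log10(max(error_rate, 1e-6))), 2, 60))
            counter += 1
            records.append(
                AlignmentRecord(
                    name=f"sim_hap{hap_idx}_{counter}",
                    ref_name=config.chrom,
                    pos=start0 + 1,
                    strand=strand,
                    cigar=cigar,
                    seq=_codes_to_str(read_codes),
                    quals=np.full(read_codes.size, q, dtype=np.int32),
                )
            )
            covered += length
    return records


def write_fastq(records: list[AlignmentRecord], path) -> None:
    """Write reads as FASTQ in sequencing orientation (reverse-strand
    reads are reverse-complemented)."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.seq
            quals = rec.quals
            if rec.strand == "-":
                seq = seq.translate(_COMP)[::-1]
                quals = quals[::-1]
            qstr = "".join(chr(min(int(q), 93) + 33) for q in quals)
            fh.write(f"@{rec.name}\n{seq}\n+\n{qstr}\n")
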