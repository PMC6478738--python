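"""Standard-format I/O and pileup construction.

Coordinates are 1-based inclusive on all public interfaces (SAM/VCF
convention); any half-open arithmetic is internal.  Multi-allelic and
indel VCF records are excluded at parse time; the analysis is
biallelic-SNV only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}

# CIGAR op codes as used internally (subset of SAM ops)
_READ_CONSUMING = frozenset("MIS=X")
_REF_CONSUMING = frozenset("MD=XN")


class FormatError(ValueError):
    """Raised for malformed input records."""


class Genotype(str, Enum):
    HOM_REF = "hom-ref"
    HET = "het"
    HOM_ALT = "hom-alt"

    @property
    def alleles(self) -> tuple[int, int]:
        return {"hom-ref": (0, 0), "het": (0, 1), "hom-alt": (1, 1)}[self.value]


@dataclass
class VariantSite:
    """A candidate biallelic SNV with genotype, quality and filter state."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    genotype: Genotype
    annotations: set[str] = field(default_factory=set)
    filter_status: list[str] = field(default_factory=list)  # empty == PASS
    phase_set: int | None = None
    hap_of_alt: int | None = None  # 1 or 2; only for phased hets
    pe: float | None = None
    sb1: int | None = None
    sb2: int | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.qual < 0:
            raise ValueError("qual must be >= 0")
        if self.hap_of_alt is not None and (
            self.genotype is not Genotype.HET or self.phase_set is None
        ):
            raise ValueError("hap_of_alt requires a het genotype and a phase set")

    @property
    def is_pass(self) -> bool:
        return not self.filter_status


@dataclass
class AlignmentRecord:
    """One primary alignment: CIGAR-equivalent ops plus sequence/qualities.

    ``seq`` is reference-oriented (as in SAM); ``pos`` is the 1-based
    leftmost reference coordinate.
    """

    name: str
    ref_name: str
    pos: int
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]]
    seq: str
    quals: np.ndarray  # phred, len == len(seq)

    _expanded: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if any(length <= 0 for _, length in self.cigar):
            raise FormatError(f"non-positive CIGAR length in read {self.name}")
        read_len = sum(n for op, n in self.cigar if op in _READ_CONSUMING)
        if read_len != len(self.seq):
            raise FormatError(
                f"CIGAR consumes {read_len} read bases but sequence of read "
                f"{self.name} has {len(self.seq)}"
            )
        if len(self.quals) != len(self.seq):
            raise FormatError(f"quality/sequence length mismatch in read {self.name}")

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    @property
    def ref_end(self) -> int:
        """1-based inclusive rightmost reference position."""
        return self.pos + self.ref_span - 1

    def expand(self):
        """Per-base alignment coordinates, all numpy.

        Returns ``(aligned_ref_pos, aligned_read_idx, deleted_ref_pos,
        n_inserted)`` where ``aligned_ref_pos`` are 1-based reference
        positions of M/=/X bases, ``aligned_read_idx`` the matching 0-based
        indices into ``seq``, and ``deleted_ref_pos`` 1-based reference
        positions covered by deletions.
        """
        if self._expanded is not None:
            return self._expanded
        ops = np.array([ord(op) for op, _ in self.cigar], dtype=np.int64)
        lens = np.array([n for _, n in self.cigar], dtype=np.int64)
        unit_ops = np.repeat(ops, lens)
        read_consuming = np.isin(unit_ops, [ord(c) for c in "MIS=X"])
        ref_consuming = np.isin(unit_ops, [ord(c) for c in "MD=XN"])
        read_idx = np.cumsum(read_consuming) - 1
        ref_pos = self.pos + np.cumsum(ref_consuming) - 1
        aligned = np.isin(unit_ops, [ord(c) for c in "M=X"])
        deleted = unit_ops == ord("D")
        n_inserted = int(np.sum(unit_ops == ord("I")))
        self._expanded = (
            ref_pos[aligned],
            read_idx[aligned],
            ref_pos[deleted],
            n_inserted,
        )
        return self._expanded


@dataclass
class PileupCounts:
    """Per-site allele tallies split by strand.

    ``ref_fwd + ref_rev`` etc.; deletion counts track reads whose alignment
    deletes the site.  Coverage excludes deletions, physical coverage
    includes them.
    """

    ref_fwd: int = 0
    ref_rev: int = 0
    alt_fwd: int = 0
    alt_rev: int = 0
    other_fwd: int = 0
    other_rev: int = 0
    del_fwd: int = 0
    del_rev: int = 0

    @property
    def n_ref(self) -> int:
        return self.ref_fwd + self.ref_rev

    @property
    def n_alt(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def n_other(self) -> int:
        return self.other_fwd + self.other_rev

    @property
    def n_del(self) -> int:
        return self.del_fwd + self.del_rev

    @property
    def coverage(self) -> int:
        """Per-base coverage (excluding deletions)."""
        return self.n_ref + self.n_alt + self.n_other

    @property
    def physical_coverage(self) -> int:
        """Per-read coverage including in-read deletions."""
        return self.coverage + self.n_del

    @property
    def deletion_fraction(self) -> float:
        phys = self.physical_coverage
        return self.n_del / phys if phys else 0.0


def parse_alignments(
    path,
    include_secondary: bool = False,
    min_mapq: int = 0,
) -> list[AlignmentRecord]:
    """Parse a SAM file into :class:`AlignmentRecord` objects.

    Secondary/supplementary alignments and unmapped reads are excluded by
    default; mapping-quality-0 reads are kept unless ``min_mapq`` says
    otherwise.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if not include_secondary and (aln.is_secondary or aln.is_supplementary):
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if aln.query_sequence is None or aln.cigartuples is None:
                raise FormatError(f"read {aln.query_name} lacks sequence or CIGAR")
            cigar = [("MIDNSHP=XB"[op], n) for op, n in aln.cigartuples]
            quals = (
                np.asarray(aln.query_qualities, dtype=np.int32)
                if aln.query_qualities is not None
                else np.full(len(aln.query_sequence), 30, dtype=np.int32)
            )
            records.append(
                AlignmentRecord(
                    name=aln.query_name,
                    ref_name=aln.reference_name,
                    pos=aln.reference_start + 1,
                    strand="-" if aln.is_reverse else "+",
                    cigar=cigar,
                    seq=aln.query_sequence.upper(),
                    quals=quals,
                )
            )
    return records


def write_sam(records: Sequence[AlignmentRecord], path, ref_lengths: dict[str, int]) -> None:
    """Write alignment records as plain-text SAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.name
            a.query_sequence = rec.seq
            a.flag = 16 if rec.strand == "-" else 0
            a.reference_id = out.header.get_tid(rec.ref_name)
            a.reference_start = rec.pos - 1
            a.mapping_quality = 60
            a.cigarstring = "".join(f"{n}{op}" for op, n in rec.cigar)
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(int(q), 93) + 33) for q in rec.quals)
            )
            out.write(a)


def _full_pileup_arrays(alignments: Iterable[AlignmentRecord], ref_length: int):
    """Genome-wide pileup: base x strand counts and deletion counts.

    Returns ``(base_counts, del_counts)`` with shapes ``(L+1, 4, 2)`` and
    ``(L+1, 2)`` indexed by 1-based position (index 0 unused) and strand
    (0 = forward, 1 = reverse).
    """
    n_cat = 10  # 4 bases x 2 strands + deletion x 2 strands
    flat = np.zeros((ref_length + 1) * n_cat, dtype=np.int64)
    chunk_pos: list[np.ndarray] = []
    chunk_units = 0

    def _flush():
        nonlocal chunk_pos, chunk_units
        if chunk_pos:
            cat = np.concatenate(chunk_pos)
            flat[:] += np.bincount(cat, minlength=flat.size)
            chunk_pos = []
            chunk_units = 0

    for rec in alignments:
        strand = 0 if rec.strand == "+" else 1
        ref_pos, read_idx, del_pos, _ = rec.expand()
        if ref_pos.size:
            if ref_pos[-1] > ref_length:
                raise IndexError(
                    f"read {rec.name} extends beyond reference end ({ref_pos[-1]} > {ref_length})"
                )
            bases = np.frombuffer(rec.seq.encode(), dtype=np.uint8)[read_idx]
            codes = np.full(bases.shape, -1, dtype=np.int64)
            for base, code in BASE_TO_CODE.items():
                codes[bases == ord(base)] = code
            valid = codes >= 0
            chunk_pos.append(
                ref_pos[valid] * n_cat + codes[valid] * 2 + strand
            )
        if del_pos.size:
            chunk_pos.append(del_pos * n_cat + 8 + strand)
        chunk_units += ref_pos.size + del_pos.size
        if chunk_units > 2_000_000:
            _flush()
    _flush()
    full = flat.reshape(ref_length + 1, n_cat)
    return full[:, :8].reshape(ref_length + 1, 4, 2), full[:, 8:]


def build_pileup(
    alignments: Sequence[AlignmentRecord],
    sites: Sequence[VariantSite],
    ref_length: int | None = None,
) -> list[PileupCounts]:
    """Tally ref/alt/other/deletion observations per site, split by strand."""
    if ref_length is None:
        ref_length = max((a.ref_end for a in alignments), default=0)
        ref_length = max(ref_length, max((s.pos for s in sites), default=0))
    for s in sites:
        if s.pos > ref_length:
            raise IndexError(f"site {s.chrom}:{s.pos} beyond reference end")
    base_counts, del_counts = _full_pileup_arrays(alignments, ref_length)
    out = []
    for s in sites:
        ref_code = BASE_TO_CODE[s.ref]
        alt_code = BASE_TO_CODE[s.alt]
        row = base_counts[s.pos]
        other = row.sum(axis=0) - row[ref_code] - row[alt_code]
        out.append(
            PileupCounts(
                ref_fwd=int(row[ref_code, 0]),
                ref_rev=int(row[ref_code, 1]),
                alt_fwd=int(row[alt_code, 0]),
                alt_rev=int(row[alt_code, 1]),
                other_fwd=int(other[0]),
                other_rev=int(other[1]),
                del_fwd=int(del_counts[s.pos, 0]),
                del_rev=int(del_counts[s.pos, 1]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    '##INFO=<ID=PE,Number=1,Type=Float,Description="Phase entropy: -log10 of the product of per-haplotype alt emission probabilities and their complements">',
    '##INFO=<ID=SB1,Number=1,Type=Integer,Description="Forward-strand reads assigned to haplotype 1 in this phase set">',
    '##INFO=<ID=SB2,Number=1,Type=Integer,Description="Forward-strand reads assigned to haplotype 2 in this phase set">',
    '##INFO=<ID=ANN,Number=.,Type=String,Description="Site annotations (homopolymer, low-coverage, high-deletion, strand-bias, low-qual, bad-phasing)">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set identifier">',
]

_KNOWN_FILTERS = [
    ("homopolymer", "SNV intersects or flanks a homopolymer run"),
    ("low-coverage", "Per-base coverage below floor"),
    ("high-deletion", "Deletion fraction at or above ceiling"),
    ("strand-bias", "Strand imbalance above phred threshold"),
    ("low-qual", "QUAL below threshold"),
    ("bad-phasing", "Phase entropy below threshold"),
]


def write_phased_vcf(
    sites: Sequence[VariantSite],
    path,
    contigs: dict[str, int],
    sample: str = "SAMPLE",
) -> None:
    """Write sites to an uncompressed VCF with PE/SB/PS/ANN tags.

    Phased hets use the ``|`` separator with alt on ``hap_of_alt``; the
    phase-set id goes into FORMAT/PS.
    """
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    for name, desc in _KNOWN_FILTERS:
        header.filters.add(name, None, None, desc)
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sorted(sites, key=lambda x: (x.chrom, x.pos)):
            rec = vcf.new_record(
                contig=s.chrom,
                start=s.pos - 1,
                stop=s.pos,
                alleles=(s.ref, s.alt),
                qual=round(s.qual, 2),
            )
            if s.filter_status:
                for f in s.filter_status:
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            if s.pe is not None:
                rec.info["PE"] = round(float(s.pe), 4)
            if s.sb1 is not None:
                rec.info["SB1"] = int(s.sb1)
            if s.sb2 is not None:
                rec.info["SB2"] = int(s.sb2)
            if s.annotations:
                rec.info["ANN"] = tuple(sorted(s.annotations))
            sample_rec = rec.samples[sample]
            if s.genotype is Genotype.HET and s.phase_set is not None:
                sample_rec["GT"] = (1, 0) if s.hap_of_alt == 1 else (0, 1)
                sample_rec.phased = True
                sample_rec["PS"] = int(s.phase_set)
            else:
                sample_rec["GT"] = s.genotype.alleles
                sample_rec.phased = False
            vcf.write(rec)


def read_vcf(path) -> list[VariantSite]:
    """Read biallelic SNV records; indels/multi-allelics are skipped.

    The number of skipped records is logged.
    """
    sites: list[VariantSite] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        sample = next(iter(vcf.header.samples), None)
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                n_skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                n_skipped += 1
                continue
            genotype = Genotype.HET
            phase_set = None
            hap_of_alt = None
            if sample is not None:
                srec = rec.samples[sample]
                gt = srec.get("GT")
                if gt is not None and None not in gt:
                    n_alt_alleles = sum(gt)
                    genotype = (
                        Genotype.HOM_REF,
                        Genotype.HET,
                        Genotype.HOM_ALT,
                    )[n_alt_alleles]
                    if genotype is Genotype.HET and srec.phased:
                        ps = srec.get("PS")
                        if ps is not None:
                            phase_set = int(ps)
                            hap_of_alt = 1 if gt[0] == 1 else 2
            filters = [f for f in rec.filter.keys() if f != "PASS"]
            info_ids = set(vcf.header.info.keys())
            pe = rec.info.get("PE") if "PE" in info_ids else None
            ann = rec.info.get("ANN") if "ANN" in info_ids else None
            sites.append(
                VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    genotype=genotype,
                    annotations=set(ann) if ann else set(),
                    filter_status=filters,
                    phase_set=phase_set,
                    hap_of_alt=hap_of_alt,
                    pe=float(pe) if pe is not None else None,
                    sb1=int(rec.info["SB1"])
                    if "SB1" in info_ids and "SB1" in rec.info else None,
                    sb2=int(rec.info["SB2"])
                    if "SB2" in info_ids and "SB2" in rec.info else None,
                )
            )
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNV records", n_skipped)
    return sites


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into name -> sequence (uppercased)."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise FormatError("FASTA sequence before header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED intervals as (chrom, start0, end) half-open tuples."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line with <3 fields: {line!r}")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return intervals
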