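"""Genomic interval plumbing and readers/writers for the standard formats.

Coordinates are 0-based, half-open (BED convention) everywhere inside the
package; GTF records are converted on read.  "Upstream"/"downstream" always
mean transcript-strand-relative orientation: for a minus-strand feature the
downstream direction is toward lower reference coordinates, and sequence
handed to motif code is reverse-complemented first.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pyfaidx

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

# Feature classes carried by GeneModel, in the default priority order used
# when a peak overlapping several classes must be assigned to exactly one.
FEATURE_PRIORITY = (
    "three_prime_utr",
    "five_prime_utr",
    "cds",
    "noncoding_exon",
    "intron",
    "downstream_flank",
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open interval [start, end) on a reference sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if not self.start < self.end:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}: {self!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class Peak:
    """A CLIP peak: an interval with an optional score and summit offset."""

    interval: GenomicInterval
    score: float = 0.0
    summit: int | None = None  # offset from interval.start, narrowPeak column 10

    @property
    def center(self) -> int:
        """Summit position when known, else interval midpoint."""
        if self.summit is not None and self.summit >= 0:
            return self.interval.start + self.summit
        return (self.interval.start + self.interval.end) // 2


@dataclass
class PeakSet:
    """Peaks from one CLIP experiment.

    ``tier`` distinguishes the union-of-replicates peak lists ("any") used for
    any-evidence binding calls from a single reproducible/IDR list
    ("reproducible") used for high-confidence analyses.
    """

    experiment_id: str
    peaks: list[Peak]
    cell_context: str = ""
    tier: str = "any"

    def __post_init__(self) -> None:
        if self.tier not in ("any", "reproducible"):
            raise ValueError(f"unknown peak tier {self.tier!r}")
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


@dataclass
class GeneModel:
    """One gene with its feature-class intervals.

    ``features`` maps a feature class name (see FEATURE_PRIORITY, plus
    "terminal_exon" and "exon") to a list of intervals.  The terminal exon is
    the transcript-3'-most exon; the 3'UTR is derived from the CDS 3' end when
    a CDS is present.
    """

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    features: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        s, e = self.span
        if not 0 <= s < e:
            raise ValueError(f"gene {self.gene_id}: bad span {self.span}")
        for cls in ("terminal_exon", "three_prime_utr"):
            for iv in self.features.get(cls, []):
                if iv.start < s or iv.end > e:
                    raise ValueError(
                        f"gene {self.gene_id}: {cls} {iv} outside span {self.span}"
                    )
        utrs = self.features.get("three_prime_utr", [])
        if utrs:
            # 3'UTRs may span several exons; the 3'-most piece must lie in the
            # terminal exon
            distal = (max(utrs, key=lambda u: u.end) if self.strand == "+"
                      else min(utrs, key=lambda u: u.start))
            if not any(
                te.start <= distal.start and distal.end <= te.end
                for te in self.features.get("terminal_exon", [])
            ):
                raise ValueError(
                    f"gene {self.gene_id}: distal 3'UTR {distal} not inside "
                    "a terminal exon"
                )

    @property
    def terminal_exon(self) -> GenomicInterval | None:
        tes = self.features.get("terminal_exon", [])
        return tes[0] if tes else None

    @property
    def three_prime_utr(self) -> GenomicInterval | None:
        utrs = self.features.get("three_prime_utr", [])
        return utrs[0] if utrs else None

    def three_prime_end(self) -> int:
        """Reference coordinate of the annotated transcript 3' end (inclusive nt)."""
        return self.span[1] - 1 if self.strand == "+" else self.span[0]


# ---------------------------------------------------------------------------
# sequence helpers

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_genome(path) -> dict[str, str]:
    """Read a FASTA into an in-memory {name: sequence} mapping."""
    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def get_sense_sequence(genome: dict[str, str], chrom: str, start: int, end: int,
                       strand: str) -> str:
    """Reference slice [start, end) in transcript (sense) orientation.

    Out-of-contig parts are truncated; truncation is logged because edge PAS
    can legitimately run off small contigs.
    """
    seq = genome[chrom]
    lo, hi = max(0, start), min(len(seq), end)
    if (lo, hi) != (start, end):
        logger.info("sequence window [%d,%d) truncated to [%d,%d) on %s",
                    start, end, lo, hi, chrom)
    if lo >= hi:
        return ""
    sub = seq[lo:hi].upper()
    return reverse_complement(sub) if strand == "-" else sub


# ---------------------------------------------------------------------------
# annotation reading

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation(path) -> list[GeneModel]:
    """Read a GTF/GFF or BED12 annotation into GeneModels.

    Per gene, the transcript with the 3'-most end is used to define the
    terminal exon and UTRs.  Unstranded records are an error; a gene_id that
    appears on more than one chromosome or strand is an error.
    """
    path = str(path)
    if path.endswith((".bed", ".bed12")):
        return _read_bed12(path)
    return _read_gtf(path)


def _parse_gtf_attrs(text: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(text))


def _read_gtf(path) -> list[GeneModel]:
    # transcript_id -> dict(gene_id, chrom, strand, exons, cds)
    tx: dict[str, dict] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{ln}: not a GTF record")
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            if ftype not in ("exon", "CDS"):
                continue
            if strand not in STRANDS:
                raise ValueError(f"{path}:{ln}: unstranded record: {line.strip()}")
            a = _parse_gtf_attrs(attrs)
            gid = a.get("gene_id")
            tid = a.get("transcript_id", gid)
            if gid is None:
                raise ValueError(f"{path}:{ln}: record lacks gene_id")
            rec = tx.setdefault(
                tid, {"gene_id": gid, "chrom": chrom, "strand": strand,
                      "exons": [], "cds": []})
            if (rec["chrom"], rec["strand"]) != (chrom, strand):
                raise ValueError(f"{path}:{ln}: transcript {tid} changes chrom/strand")
            iv = (int(start) - 1, int(end))  # GTF is 1-based inclusive
            rec["exons" if ftype == "exon" else "cds"].append(iv)
    # group transcripts by gene
    genes: dict[str, list[dict]] = {}
    for rec in tx.values():
        genes.setdefault(rec["gene_id"], []).append(rec)
    out = []
    for gid, recs in genes.items():
        if len({(r["chrom"], r["strand"]) for r in recs}) > 1:
            raise ValueError(f"duplicate gene_id {gid!r} on multiple chrom/strands")
        out.append(_build_gene(gid, recs))
    return out


def _build_gene(gid: str, recs: list[dict]) -> GeneModel:
    chrom = recs[0]["chrom"]
    strand = recs[0]["strand"]
    span_start = min(min(s for s, _ in r["exons"]) for r in recs)
    span_end = max(max(e for _, e in r["exons"]) for r in recs)
    # representative transcript: the one reaching the 3'-most end
    if strand == "+":
        rep = max(recs, key=lambda r: max(e for _, e in r["exons"]))
    else:
        rep = min(recs, key=lambda r: min(s for s, _ in r["exons"]))
    exons = sorted(rep["exons"])
    cds = sorted(rep["cds"])
    feats = _features_from_blocks(chrom, strand, exons, cds)
    feats["exon"] = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    return GeneModel(gid, chrom, strand, (span_start, span_end), feats)


def _features_from_blocks(chrom: str, strand: str,
                          exons: list[tuple[int, int]],
                          cds: list[tuple[int, int]]) -> dict[str, list[GenomicInterval]]:
    """Derive terminal exon, UTRs, CDS pieces and introns from exon/CDS blocks."""
    iv = lambda s, e: GenomicInterval(chrom, s, e, strand)
    feats: dict[str, list[GenomicInterval]] = {}
    term = exons[-1] if strand == "+" else exons[0]
    feats["terminal_exon"] = [iv(*term)]
    feats["intron"] = [iv(a_end, b_start)
                       for (_, a_end), (b_start, _) in zip(exons, exons[1:])
                       if b_start > a_end]
    if not cds:
        feats["noncoding_exon"] = [iv(s, e) for s, e in exons]
        return feats
    feats["cds"] = [iv(s, e) for s, e in cds]
    cds_lo = min(s for s, _ in cds)
    cds_hi = max(e for _, e in cds)
    utr3, utr5 = [], []
    for s, e in exons:
        if strand == "+":
            if e > cds_hi:
                utr3.append((max(s, cds_hi), e))
            if s < cds_lo:
                utr5.append((s, min(e, cds_lo)))
        else:
            if s < cds_lo:
                utr3.append((s, min(e, cds_lo)))
            if e > cds_hi:
                utr5.append((max(s, cds_hi), e))
    feats["three_prime_utr"] = [iv(s, e) for s, e in utr3 if s < e]
    feats["five_prime_utr"] = [iv(s, e) for s, e in utr5 if s < e]
    return feats


def _read_bed12(path) -> list[GeneModel]:
    out = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: BED12 record needs 12 columns")
            chrom, cstart, cend, name, _, strand = f[:6]
            if strand not in STRANDS:
                raise ValueError(f"{path}:{ln}: unstranded record: {name}")
            if name in seen:
                raise ValueError(f"{path}:{ln}: duplicate gene_id {name!r}")
            seen.add(name)
            cstart = int(cstart)
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = sorted((cstart + o, cstart + o + sz)
                           for o, sz in zip(starts, sizes))
            cds_blocks = []
            if thick_e > thick_s:  # thickStart==thickEnd marks non-coding
                for s, e in exons:
                    s2, e2 = max(s, thick_s), min(e, thick_e)
                    if s2 < e2:
                        cds_blocks.append((s2, e2))
            feats = _features_from_blocks(chrom, strand, exons, cds_blocks)
            feats["exon"] = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
            out.append(GeneModel(name, chrom, strand,
                                 (exons[0][0], exons[-1][1]), feats))
    return out


def extend_annotation_downstream(genes: list[GeneModel],
                                 extension: int) -> list[GeneModel]:
    """Grow each gene span past its 3' end and record a downstream flank.

    The eCLIP peak caller only searches within annotated gene boundaries, so
    binding downstream of the cleavage site (CstF territory) is missed unless
    the annotation is extended; the standard extension is 500 nt.  Exon and
    UTR features are left untouched.  A minus-strand extension that would run
    past the contig origin is clamped at 0 and logged.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    out = []
    for g in genes:
        s, e = g.span
        feats = {k: list(v) for k, v in g.features.items()}
        if extension > 0:
            if g.strand == "+":
                flank = GenomicInterval(g.chrom, e, e + extension, "+")
                span = (s, e + extension)
            else:
                new_s = s - extension
                if new_s < 0:
                    logger.warning("gene %s: downstream extension clamped at 0", g.gene_id)
                    new_s = 0
                span = (new_s, e)
                flank = GenomicInterval(g.chrom, new_s, s, "-") if new_s < s else None
            if flank is not None:
                feats.setdefault("downstream_flank", []).append(flank)
        else:
            span = (s, e)
        out.append(GeneModel(g.gene_id, g.chrom, g.strand, span, feats))
    return out


# ---------------------------------------------------------------------------
# interval overlap

def intersect_peaks(peaks: PeakSet | list[GenomicInterval],
                    features: list[GenomicInterval],
                    stranded: bool = True) -> tuple[np.ndarray, list[list[int]]]:
    """Overlap peaks with features.

    Returns ``(bound, assignment)``: ``bound[j]`` is True iff feature *j* is
    overlapped by >=1 peak by >=1 nt on the same strand (when ``stranded``);
    ``assignment[i]`` lists the indices of every feature peak *i* overlaps.
    Warns if the two inputs share no chromosome names.
    """
    pivs = peaks.intervals() if isinstance(peaks, PeakSet) else list(peaks)
    bound = np.zeros(len(features), dtype=bool)
    assignment: list[list[int]] = [[] for _ in pivs]
    if pivs and features:
        pchroms = {p.chrom for p in pivs}
        fchroms = {f.chrom for f in features}
        if not (pchroms & fchroms):
            warnings.warn(
                "no shared chromosome names between peaks and features: "
                f"peaks={sorted(pchroms)} features={sorted(fchroms)}")
    # group features per (chrom[,strand]) into numpy arrays, scan per peak
    groups: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for key in {(f.chrom, f.strand if stranded else None) for f in features}:
        idx = np.array([j for j, f in enumerate(features)
                        if (f.chrom, f.strand if stranded else None) == key])
        starts = np.array([features[j].start for j in idx])
        ends = np.array([features[j].end for j in idx])
        groups[key] = (idx, starts, ends)
    for i, p in enumerate(pivs):
        key = (p.chrom, p.strand if stranded else None)
        if key not in groups:
            continue
        idx, starts, ends = groups[key]
        hit = (starts < p.end) & (p.start < ends)
        hits = idx[hit]
        bound[hits] = True
        assignment[i] = hits.tolist()
    return bound, assignment


def merge_intervals(intervals: list[GenomicInterval],
                    stranded: bool = True) -> list[GenomicInterval]:
    """Merge overlapping/abutting intervals per (chrom[, strand])."""
    keyed: dict[tuple, list[GenomicInterval]] = {}
    for iv in intervals:
        keyed.setdefault((iv.chrom, iv.strand if stranded else "+"), []).append(iv)
    out = []
    for (chrom, strand), ivs in sorted(keyed.items()):
        ivs = sorted(ivs, key=lambda x: x.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e, strand))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e, strand))
    return out


# ---------------------------------------------------------------------------
# BED / narrowPeak / GTF writers and readers

def read_bed6(path) -> list[tuple[GenomicInterval, str, float]]:
    """Read BED6 records as (interval, name, score) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "+"
            out.append((GenomicInterval(chrom, start, end, strand), name, score))
    return out


def write_bed6(records, path, header_comment: str | None = None) -> None:
    """Write (interval, name, score) tuples (or bare intervals) as BED6."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for rec in records:
            if isinstance(rec, GenomicInterval):
                iv, name, score = rec, ".", 0
            else:
                iv, name, score = rec
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def read_narrowpeak(path, experiment_id: str = "", cell_context: str = "",
                    tier: str = "any") -> PeakSet:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5])
            score = float(f[6]) if len(f) > 6 else 0.0
            summit = int(f[9]) if len(f) > 9 else -1
            peaks.append(Peak(iv, score, summit if summit >= 0 else None))
    return PeakSet(experiment_id or str(path), peaks, cell_context, tier)


def write_narrowpeak(peakset: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peakset.peaks):
            iv = p.interval
            summit = p.summit if p.summit is not None else -1
            fh.write("\t".join(map(str, [
                iv.chrom, iv.start, iv.end, f"{peakset.experiment_id}_{i}",
                0, iv.strand, f"{p.score:g}", -1, -1, summit])) + "\n")


def write_gtf(genes: list[GeneModel], path, source: str = "apamap") -> None:
    """Write gene models as GTF (exon + CDS records, 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            rows = [(iv, "exon") for iv in g.features.get("exon", [])]
            rows += [(iv, "CDS") for iv in g.features.get("cds", [])]
            for iv, ftype in sorted(rows, key=lambda r: r[0].start):
                fh.write("\t".join(map(str, [
                    g.chrom, source, ftype, iv.start + 1, iv.end, ".",
                    g.strand, ".", attrs])) + "\n")
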