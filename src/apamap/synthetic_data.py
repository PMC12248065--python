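"""Fully ground-truthed synthetic data for every pipeline stage.

The generator emulates the statistical structure targeted 3'-end sequencing
assumes: terminal exons carrying >=2 polyadenylation sites whose relative
usage shifts between conditions, cleavage imprecision as bounded discrete
jitter around each PAS, oligo-dT internal-priming artifacts as genomic A-runs
that attract reads, eCLIP peaks planted at controlled offsets from chosen
PAS, and PAS signal architecture (AAUAAA/AUUAAA hexamer 10-20 nt upstream of
the cleavage site, UGUA enhancer at a configurable distance upstream of the
hexamer, a CA cleavage dinucleotide, a GU-rich downstream element).

Every planted property is recorded in :class:`GroundTruth`; downstream tests
read labels only from there.  A fixed ``rng_seed`` gives byte-identical
outputs (all sampling goes through integer-seeded ``numpy`` generators).

Sequence hygiene: background A-runs are capped at 3 nt inside gene bodies and
accidental UGUA/hexamer occurrences are scrubbed from a window around each
true PAS, so that planted internal-priming labels and motif spacings are the
*only* instances the pipeline can recover.  Real 3'UTRs are messier; see
docs/methods.md for what this does and does not validate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io_core import (
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    reverse_complement,
)

# fixed gene architecture (sense coordinates, nt)
FIVE_UTR_LEN = 50
EXON1_LEN = 250
INTRON_LEN = 100
CDS_INTO_TERMINAL = 30
UTR_OFFSET = EXON1_LEN + INTRON_LEN + CDS_INTO_TERMINAL  # 3'UTR start
TAIL = 40  # nt kept 3' of the distal cleavage site
DSE = "TGTGTTGTGT"  # GU-rich downstream element written after each cleavage site

HEXAMERS_DNA = ("AATAAA", "ATTAAA")
UGUA_DNA = "TGTA"


@dataclass
class SimConfig:
    """One scenario: genome geometry, usage shifts, noise and peak plan.

    Usage fractions are per-PAS (proximal -> distal) and must sum to 1.
    ``delta_usage`` is the planted knockdown shift of distal-PAS usage;
    planted "lengthening" events move it from distal to proximal on KD.
    ``bound_fraction=None`` binds exactly the planted-shift genes (the
    geometry the positional-enrichment analyses assume); a float binds a
    random gene fraction instead.
    """

    n_genes: int = 200
    pas_per_exon: int = 2
    utr_length: tuple[int, int] = (420, 600)
    depth: float = 500.0
    usage_control: tuple[float, ...] = (0.5, 0.5)
    delta_usage: float = 0.30
    frac_shift: float = 0.5
    frac_cyto_specific: float = 0.0
    frac_nuc_specific: float = 0.0
    jitter_max: int = 5
    priming_artifact_rate: float = 0.10
    artifact_read_fraction: float = 0.15
    artifact_run_length: int = 18
    hexamer_gap: tuple[int, int] = (10, 20)
    ugua_distance: int = 50
    linker_gc: float | None = None
    gc_content: float = 0.45
    bound_fraction: float | None = None
    peak_offset_center: int = -50
    peak_offset_jitter: int = 0
    peak_halfwidth: int = 15
    background_peak_rate: float = 0.2
    n_replicates: int = 3
    conditions: tuple[str, str] = ("control", "kd")
    compartments: tuple[str, ...] = ("whole",)
    dpdui_noise: float = 0.01
    gene_spacing: int = 500
    chrom_name: str = "chrS"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.utr_length = tuple(self.utr_length)
        self.usage_control = tuple(self.usage_control)
        self.hexamer_gap = tuple(self.hexamer_gap)
        self.conditions = tuple(self.conditions)
        self.compartments = tuple(self.compartments)
        if self.pas_per_exon < 2:
            raise ValueError("pas_per_exon must be >= 2")
        if len(self.usage_control) != self.pas_per_exon:
            raise ValueError("usage_control length must equal pas_per_exon")
        if abs(sum(self.usage_control) - 1.0) > 1e-9:
            raise ValueError("usage_control must sum to 1")
        if self.jitter_max < 0:
            raise ValueError("jitter_max must be >= 0")
        if not 0 <= self.priming_artifact_rate <= 1:
            raise ValueError("priming_artifact_rate must be in [0,1]")
        if self.artifact_run_length < 7:
            raise ValueError("artifact_run_length must be >= 7 (A-run definition)")
        # the KD shift moves mass between proximal and distal; both shifted
        # vectors must remain valid fractions
        if self.delta_usage < 0 or (
            self.delta_usage > min(self.usage_control[-1], 1 - self.usage_control[0])
            and self.frac_shift + self.frac_cyto_specific + self.frac_nuc_specific > 0
        ) or (
            self.delta_usage > min(self.usage_control[0], 1 - self.usage_control[-1])
            and self.frac_shift > 0
        ):
            raise ValueError("delta_usage incompatible with usage_control")
        self._validate_geometry()

    # upstream room one PAS needs for its planted signal architecture
    @property
    def upstream_footprint(self) -> int:
        return self.ugua_distance + 4 + 6 + self.hexamer_gap[1] + 15

    def _validate_geometry(self) -> None:
        utr_min = self.utr_length[0]
        distal_rel = utr_min - TAIL
        room = self.upstream_footprint
        if self.pas_per_exon > 1:
            spacing = (distal_rel - room) / (self.pas_per_exon - 1)
            if spacing < room + 2 * self.jitter_max + 20:
                raise ValueError(
                    f"UTR too short: min UTR {utr_min} nt cannot hold "
                    f"{self.pas_per_exon} PAS with a {room} nt signal footprint each"
                )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PASTruth:
    """Planted geometry of one true polyadenylation site."""

    position: int  # genomic coordinate of the cleavage nucleotide
    sense_position: int  # position within the gene-local sense sequence
    hexamer: str  # RNA alphabet, AAUAAA or AUUAAA
    hexamer_interval: GenomicInterval
    ugua_interval: GenomicInterval
    hexamer_gap: int  # nt between hexamer 3' end and the cleavage nt
    ugua_gap: int  # nt between UGUA 3' end and the hexamer 5' start


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    terminal_exon: GenomicInterval
    pas: list[PASTruth]  # proximal -> distal in transcript orientation
    usage: dict[tuple[str, str], tuple[float, ...]]  # (condition, compartment)
    event_class: str  # shift_lengthen | shift_shorten | null | cyto_specific | nuc_specific
    true_delta_distal: float  # KD - control distal usage (first compartment)
    dpdui_class: str  # rbp_lengthens | rbp_shortens | non_changing
    decoy_position: int | None  # genomic read site of the planted A-run artifact
    decoy_sense_position: int | None
    bound: bool
    peak_target_pas: int | None  # index into pas (distal by default)


@dataclass
class GroundTruth:
    config: SimConfig
    genes: dict[str, GeneTruth] = field(default_factory=dict)

    def gene_ids(self, event_class: str | None = None) -> list[str]:
        return [g for g, t in self.genes.items()
                if event_class is None or t.event_class == event_class]

    @property
    def n_bound(self) -> int:
        return sum(t.bound for t in self.genes.values())


# ---------------------------------------------------------------------------
# genome simulation

def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Random sequence at the given GC with A-runs capped at 3 nt."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)
    run = 0
    for i in range(n):
        if arr[i] == b"A":
            run += 1
            if run > 3:
                arr[i] = b"C"
                run = 0
        else:
            run = 0
    return arr


def _scrub_motifs(seq: list, lo: int, hi: int, protected: set[int]) -> None:
    """Replace accidental UGUA/hexamer occurrences in seq[lo:hi] with C.

    Planted instances (whose bases are all in ``protected``) are kept.  C
    occurs in none of the scrubbed motifs, so replacement cannot create a new
    occurrence; a single left-to-right pass suffices.
    """
    motifs = (UGUA_DNA,) + HEXAMERS_DNA
    text = "".join(seq[max(0, lo):hi])
    base = max(0, lo)
    for m in motifs:
        start = 0
        while True:
            j = text.find(m, start)
            if j < 0:
                break
            pos = base + j
            sites = range(pos, pos + len(m))
            if not all(s in protected for s in sites):
                for s in sites:
                    if s not in protected:
                        seq[s] = "C"
                        break
                text = text[:j] + "".join(seq[base + j: base + j + len(m)]) + text[j + len(m):]
            start = j + 1


def _scrub_both_orientations(seq: list, max_rounds: int = 10) -> None:
    """Remove every UGUA/hexamer occurrence on either strand of a spacer.

    Inter-gene spacers fall inside the motif-analysis windows of edge PAS on
    both neighbouring genes (either orientation), so they must carry no
    analysed motif at all.  Replacement can in principle create a new
    C-containing occurrence, hence the fixpoint loop.
    """
    motifs = (UGUA_DNA,) + HEXAMERS_DNA
    motifs = motifs + tuple(reverse_complement(m) for m in motifs)
    for _ in range(max_rounds):
        text = "".join(seq)
        dirty = False
        for m in motifs:
            j = text.find(m)
            while j >= 0:
                seq[j] = "C" if m[0] != "C" else "G"
                dirty = True
                text = text[:j] + seq[j] + text[j + 1:]
                j = text.find(m, j + 1)
        if not dirty:
            return


def _assign_classes(cfg: SimConfig, rng: np.random.Generator) -> list[str]:
    n = cfg.n_genes
    n_shift = round(cfg.frac_shift * n)
    n_cyto = round(cfg.frac_cyto_specific * n)
    n_nuc = round(cfg.frac_nuc_specific * n)
    if n_shift + n_cyto + n_nuc > n:
        raise ValueError("event-class fractions exceed 1")
    classes = (["shift_lengthen"] * ((n_shift + 1) // 2)
               + ["shift_shorten"] * (n_shift // 2)
               + ["cyto_specific"] * n_cyto
               + ["nuc_specific"] * n_nuc)
    classes += ["null"] * (n - len(classes))
    order = rng.permutation(n)
    return [classes[i] for i in np.argsort(order)]


def _usage_vectors(cfg: SimConfig, event_class: str) -> dict[tuple[str, str], tuple[float, ...]]:
    base = np.array(cfg.usage_control, dtype=float)
    shifted_to_proximal = base.copy()
    shifted_to_proximal[0] += cfg.delta_usage
    shifted_to_proximal[-1] -= cfg.delta_usage
    shifted_to_distal = base.copy()
    shifted_to_distal[0] -= cfg.delta_usage
    shifted_to_distal[-1] += cfg.delta_usage
    usage: dict[tuple[str, str], tuple[float, ...]] = {}
    ctrl, kd = cfg.conditions
    for comp in cfg.compartments:
        usage[(ctrl, comp)] = tuple(base)
        if event_class == "shift_lengthen":
            kd_vec = shifted_to_proximal
        elif event_class == "shift_shorten":
            kd_vec = shifted_to_distal
        elif event_class == "cyto_specific":
            kd_vec = shifted_to_proximal if comp == "cytoplasmic" else base
        elif event_class == "nuc_specific":
            kd_vec = shifted_to_proximal if comp == "nuclear" else base
        else:
            kd_vec = base
        usage[(kd, comp)] = tuple(kd_vec)
    return usage


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel], GroundTruth]:
    """Build the genome, its annotation, and the ground-truth record.

    Each gene is laid out 5'->3' in sense coordinates (first exon, intron,
    terminal exon whose 3'UTR carries the planted PAS architecture), then
    written onto the chromosome forward or reverse-complemented depending on
    the gene's strand (strands alternate).
    """
    cfg = config
    rng = np.random.default_rng([cfg.rng_seed, 1])
    classes = _assign_classes(cfg, rng)

    n_decoy = round(cfg.priming_artifact_rate * cfg.n_genes)
    decoy_genes = set(rng.permutation(cfg.n_genes)[:n_decoy].tolist())
    if cfg.bound_fraction is None:
        bound_genes = {i for i, c in enumerate(classes) if c.startswith("shift")}
    else:
        n_bound = round(cfg.bound_fraction * cfg.n_genes)
        bound_genes = set(rng.permutation(cfg.n_genes)[:n_bound].tolist())

    chrom_parts: list[np.ndarray] = []
    cursor = 0
    genes: list[GeneModel] = []
    truth = GroundTruth(config=cfg)
    ctrl, kd = cfg.conditions

    for gi in range(cfg.n_genes):
        gid = f"g{gi:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        utr_len = int(rng.integers(cfg.utr_length[0], cfg.utr_length[1] + 1))
        L = UTR_OFFSET + utr_len

        seq = _background(rng, L, cfg.gc_content)
        seq = [chr(b[0]) for b in seq]  # mutable list of chars

        # PAS sense positions, proximal -> distal
        distal = L - TAIL
        room = cfg.upstream_footprint
        first = UTR_OFFSET + room
        if cfg.pas_per_exon > 1:
            pas_sense = np.linspace(first, distal, cfg.pas_per_exon)
            pas_sense = [int(round(x)) for x in pas_sense]
        else:
            pas_sense = [distal]

        protected: set[int] = set()
        pas_records: list[dict] = []
        for k, p in enumerate(pas_sense):
            gap = int(rng.integers(cfg.hexamer_gap[0], cfg.hexamer_gap[1] + 1))
            hexamer = HEXAMERS_DNA[k % 2]
            hex_start = p - gap - 6
            ug_start = hex_start - cfg.ugua_distance - 4
            if ug_start < UTR_OFFSET - CDS_INTO_TERMINAL:
                raise ValueError(f"gene {gid}: UTR too short for PAS {k} architecture")
            seq[hex_start:hex_start + 6] = list(hexamer)
            seq[ug_start:ug_start + 4] = list(UGUA_DNA)
            if cfg.linker_gc is not None:
                linker = _background(rng, hex_start - (ug_start + 4), cfg.linker_gc)
                seq[ug_start + 4:hex_start] = [chr(b[0]) for b in linker]
            seq[p - 1:p + 1] = ["C", "A"]
            seq[p + 1:p + 1 + len(DSE)] = list(DSE)
            protected.update(range(ug_start, ug_start + 4))
            protected.update(range(hex_start, hex_start + 6))
            protected.update(range(p - 1, p + 1 + len(DSE)))
            pas_records.append({"sense": p, "gap": gap, "hexamer": hexamer,
                                "hex_start": hex_start, "ug_start": ug_start})

        # planted internal-priming decoy: an A-run with reads primed at its 5' edge
        decoy_sense = None
        if gi in decoy_genes:
            lo = pas_records[0]["sense"] + len(DSE) + 30
            hi = pas_records[-1]["ug_start"] - 30 - cfg.artifact_run_length
            if hi <= lo:
                raise ValueError(f"gene {gid}: no room for decoy A-run between PAS")
            decoy_sense = (lo + hi) // 2
            run = range(decoy_sense + 1, decoy_sense + 1 + cfg.artifact_run_length)
            for s in run:
                seq[s] = "A"
            protected.update(run)
            protected.add(decoy_sense)

        # scrub accidental motif hits around each true PAS (spacing-analysis window)
        for rec in pas_records:
            _scrub_motifs(seq, rec["sense"] - 170, min(L, rec["sense"] + 160), protected)

        sense_seq = "".join(seq)
        gstart = cursor
        genomic = sense_seq if strand == "+" else reverse_complement(sense_seq)
        chrom_parts.append(np.frombuffer(genomic.encode(), dtype="S1"))
        spacer = [chr(b[0]) for b in _background(rng, cfg.gene_spacing, cfg.gc_content)]
        _scrub_both_orientations(spacer)
        chrom_parts.append(np.frombuffer("".join(spacer).encode(), dtype="S1"))
        cursor += L + cfg.gene_spacing

        def g_pos(s: int) -> int:
            return gstart + s if strand == "+" else gstart + L - 1 - s

        def g_iv(s1: int, s2: int) -> GenomicInterval:
            if strand == "+":
                return GenomicInterval(cfg.chrom_name, gstart + s1, gstart + s2, "+")
            return GenomicInterval(cfg.chrom_name, gstart + L - s2, gstart + L - s1, "-")

        exon1 = g_iv(0, EXON1_LEN)
        term = g_iv(EXON1_LEN + INTRON_LEN, L)
        feats = {
            "exon": sorted([exon1, term], key=lambda x: x.start),
            "terminal_exon": [term],
            "five_prime_utr": [g_iv(0, FIVE_UTR_LEN)],
            "cds": sorted([g_iv(FIVE_UTR_LEN, EXON1_LEN),
                           g_iv(EXON1_LEN + INTRON_LEN, UTR_OFFSET)],
                          key=lambda x: x.start),
            "intron": [g_iv(EXON1_LEN, EXON1_LEN + INTRON_LEN)],
            "three_prime_utr": [g_iv(UTR_OFFSET, L)],
        }
        genes.append(GeneModel(gid, cfg.chrom_name, strand, (gstart, gstart + L), feats))

        pas_truth = [
            PASTruth(
                position=g_pos(rec["sense"]),
                sense_position=rec["sense"],
                hexamer=rec["hexamer"].replace("T", "U"),
                hexamer_interval=g_iv(rec["hex_start"], rec["hex_start"] + 6),
                ugua_interval=g_iv(rec["ug_start"], rec["ug_start"] + 4),
                hexamer_gap=rec["gap"],
                ugua_gap=cfg.ugua_distance,
            )
            for rec in pas_records
        ]
        ev = classes[gi]
        usage = _usage_vectors(cfg, ev)
        comp0 = cfg.compartments[0]
        delta_distal = usage[(kd, comp0)][-1] - usage[(ctrl, comp0)][-1]
        if delta_distal < 0:
            dpdui_class = "rbp_lengthens"  # KD loses distal usage => dPDUI > 0
        elif delta_distal > 0:
            dpdui_class = "rbp_shortens"
        else:
            dpdui_class = "non_changing"
        truth.genes[gid] = GeneTruth(
            gene_id=gid, chrom=cfg.chrom_name, strand=strand,
            terminal_exon=term, pas=pas_truth, usage=usage, event_class=ev,
            true_delta_distal=delta_distal, dpdui_class=dpdui_class,
            decoy_position=g_pos(decoy_sense) if decoy_sense is not None else None,
            decoy_sense_position=decoy_sense,
            bound=gi in bound_genes,
            peak_target_pas=(cfg.pas_per_exon - 1) if gi in bound_genes else None,
        )

    genome = {cfg.chrom_name: b"".join(
        part.tobytes() for part in chrom_parts).decode()}
    return genome, genes, truth


# ---------------------------------------------------------------------------
# 3'-end read simulation

def default_samples(config: SimConfig) -> list[tuple[str, str, int]]:
    return [(cond, comp, rep)
            for cond, comp, rep in itertools.product(
                config.conditions, config.compartments,
                range(1, config.n_replicates + 1))]


def sample_id(condition: str, compartment: str, replicate: int) -> str:
    return f"{condition}_{compartment}_rep{replicate}"


def make_manifest(samples: list[tuple[str, str, int]]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample": sample_id(*s), "condition": s[0], "compartment": s[1],
          "replicate": s[2]} for s in samples])


def simulate_endseq(config: SimConfig, truth: GroundTruth,
                    samples: list[tuple[str, str, int]] | None = None,
                    ) -> dict[str, pd.DataFrame]:
    """Draw per-sample single-nucleotide read 3'-end positions.

    Per exon and sample the read count is Poisson(depth); reads are assigned
    to PAS by the condition/compartment usage vector (multinomial) and their
    positions jittered by a symmetric discrete uniform offset of at most
    ``jitter_max``.  Genes with a planted decoy additionally receive
    Poisson(depth * artifact_read_fraction) reads at the decoy site.  Each
    sample (replicate index included) gets its own deterministic RNG stream.
    """
    cfg = config
    if samples is None:
        samples = default_samples(cfg)
    out: dict[str, pd.DataFrame] = {}
    for si, (cond, comp, rep) in enumerate(samples):
        rng = np.random.default_rng([cfg.rng_seed, 2, si])
        rows_pos: list[np.ndarray] = []
        rows_strand: list[str] = []
        for gid, gt in truth.genes.items():
            usage = np.array(gt.usage[(cond, comp)])
            n = rng.poisson(cfg.depth)
            counts = rng.multinomial(n, usage) if n > 0 else np.zeros(len(usage), int)
            for k, c in enumerate(counts):
                if c == 0:
                    continue
                jit = (rng.integers(-cfg.jitter_max, cfg.jitter_max + 1, size=c)
                       if cfg.jitter_max > 0 else np.zeros(c, int))
                sense = gt.pas[k].sense_position + jit
                rows_pos.append(_sense_to_genomic(gt, sense))
                rows_strand.extend([gt.strand] * c)
            if gt.decoy_sense_position is not None and cfg.artifact_read_fraction > 0:
                c = rng.poisson(cfg.depth * cfg.artifact_read_fraction)
                if c > 0:
                    jit = (rng.integers(-cfg.jitter_max, cfg.jitter_max + 1, size=c)
                           if cfg.jitter_max > 0 else np.zeros(c, int))
                    sense = gt.decoy_sense_position + jit
                    rows_pos.append(_sense_to_genomic(gt, sense))
                    rows_strand.extend([gt.strand] * c)
        pos = np.concatenate(rows_pos) if rows_pos else np.array([], dtype=int)
        df = pd.DataFrame({
            "chrom": cfg.chrom_name, "pos": pos, "strand": rows_strand,
        })
        out[sample_id(cond, comp, rep)] = df
    return out


def _sense_to_genomic(gt: GeneTruth, sense: np.ndarray) -> np.ndarray:
    p0 = gt.pas[0]
    # genomic = a + b * sense, with b = strand sign
    if gt.strand == "+":
        return p0.position - p0.sense_position + sense
    return p0.position + p0.sense_position - sense


def write_endseq_bed(reads: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, strand in reads.itertuples(index=False):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t0\t{strand}\n")


def read_endseq_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), f[5] if len(f) > 5 else "+"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


# ---------------------------------------------------------------------------
# peaks, reference PAS, dPDUI tables, TPM

def simulate_peaks(config: SimConfig, truth: GroundTruth,
                   experiment_id: str = "simRBP", tier: str = "reproducible",
                   ) -> PeakSet:
    """Plant one peak per bound gene at the configured offset from its target PAS.

    The offset is transcript-strand-relative (negative = upstream of the PAS);
    unbound genes receive a background peak in their CDS region at rate
    ``background_peak_rate``.
    """
    cfg = config
    rng = np.random.default_rng([cfg.rng_seed, 3])
    peaks: list[Peak] = []
    hw = cfg.peak_halfwidth
    for gid, gt in truth.genes.items():
        if gt.bound:
            target = gt.pas[gt.peak_target_pas]
            off = cfg.peak_offset_center
            if cfg.peak_offset_jitter > 0:
                off += int(rng.integers(-cfg.peak_offset_jitter,
                                        cfg.peak_offset_jitter + 1))
            center_sense = target.sense_position + off
            peaks.append(_sense_peak(gt, center_sense, hw, float(rng.uniform(1, 10))))
        elif rng.random() < cfg.background_peak_rate:
            center_sense = FIVE_UTR_LEN + int(rng.integers(0, EXON1_LEN - FIVE_UTR_LEN))
            peaks.append(_sense_peak(gt, center_sense, hw, float(rng.uniform(0.1, 1))))
    return PeakSet(experiment_id, peaks, tier=tier)


def _sense_peak(gt: GeneTruth, center_sense: int, hw: int, score: float) -> Peak:
    center = int(_sense_to_genomic(gt, np.array([center_sense]))[0])
    iv = GenomicInterval(gt.chrom, center - hw, center + hw + 1, gt.strand)
    return Peak(iv, score=score, summit=center - iv.start)


def reference_pas_records(truth: GroundTruth, slop: int = 10,
                          ) -> list[tuple[GenomicInterval, str, float]]:
    """True PAS as a reference database track (clustered +/- slop windows).

    Decoy artifact sites are deliberately absent, mirroring internal-priming-
    free reference PAS databases.
    """
    recs = []
    for gid, gt in truth.genes.items():
        for k, p in enumerate(gt.pas):
            iv = GenomicInterval(gt.chrom, max(0, p.position - slop),
                                 p.position + slop + 1, gt.strand)
            recs.append((iv, f"{gid}_pas{k}", 0.0))
    return recs


def simulate_dpdui_table(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """DaPars-style table: PDUI per condition, dPDUI and an adjusted p per exon.

    PDUI is the distal-PAS usage fraction; dPDUI = PDUI_control - PDUI_kd, so
    planted events where the depleted protein normally promotes the distal
    site (3'UTR lengthening) read dPDUI >= +delta.  Adjusted p-values are
    *generated*, small for planted events and > 0.05 otherwise; the
    classification layer only thresholds them.
    """
    cfg = config
    rng = np.random.default_rng([cfg.rng_seed, 4])
    ctrl, kd = cfg.conditions
    comp = cfg.compartments[0]
    rows = []
    for gid, gt in truth.genes.items():
        if len(gt.pas) < 2:
            continue
        pdui_c = gt.usage[(ctrl, comp)][-1]
        pdui_k = gt.usage[(kd, comp)][-1]
        if cfg.dpdui_noise > 0:
            pdui_c = float(np.clip(pdui_c + rng.normal(0, cfg.dpdui_noise), 0, 1))
            pdui_k = float(np.clip(pdui_k + rng.normal(0, cfg.dpdui_noise), 0, 1))
        if gt.dpdui_class == "non_changing":
            p_adj = float(rng.uniform(0.051, 1.0))
        else:
            p_adj = float(rng.uniform(1e-8, 0.049))
        rows.append({"exon_id": f"{gid}_te", "gene_id": gid,
                     "PDUI_ctrl": pdui_c, "PDUI_kd": pdui_k,
                     "dPDUI": pdui_c - pdui_k, "p_adj": p_adj})
    return pd.DataFrame(rows)


def make_tpm_table(truth: GroundTruth, n_controls: int = 3,
                   low_fraction: float = 0.1) -> pd.DataFrame:
    """Control-replicate TPM table; a fraction of genes is below 1 TPM."""
    cfg = truth.config
    rng = np.random.default_rng([cfg.rng_seed, 5])
    gids = list(truth.genes)
    n_low = round(low_fraction * len(gids))
    low = set(rng.permutation(len(gids))[:n_low].tolist())
    rows = []
    for i, gid in enumerate(gids):
        base = rng.uniform(0.05, 0.5) if i in low else rng.uniform(2.0, 200.0)
        vals = base * rng.uniform(0.8, 1.2, size=n_controls)
        rows.append({"gene_id": gid, **{f"control_rep{r+1}": v
                                        for r, v in enumerate(vals)}})
    return pd.DataFrame(rows)
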