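"""Gene-neighborhood analysis: operon structures, ORF1 candidates, summaries.

The screening combines per-gene calls (tRNA identity typing, aaRS lineage
typing) with GFF3 coordinates to detect the characteristic gene clusters:
a tRNA-Trp(A73)/ORF1/TrpRS-A1 operon, optionally followed by a bacteria-type
TrpRS gene or headed by a trp repressor gene, and the looser archaeal
TrpRS-A2 / TrpRS-A-like clusters. The locus grammar operates on abstract
role labels, so the simulator can compute ground truth with the same grammar
applied to the true labels while detection recomputes roles from sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import aars as A
from . import cloverleaf as C
from .trna_template import revcomp

# role labels (transcription-order grammar alphabet)
TRNA_TRP_A = "TRNA_TRP_A"        # tRNA-Trp with archaeal identity (A73, G1-C72)
TRNA_TRP_BACT = "TRNA_TRP_BACT"
TRNA_TYR = "TRNA_TYR"
ORF1 = "ORF1"
TRPRS_A1 = "TRPRS_A1"
TRPRS_A2 = "TRPRS_A2"
TRPRS_ALIKE = "TRPRS_ALIKE"
TRPRS_BACT = "TRPRS_BACT"
TRPR = "TRPR"                    # trp repressor (label-recognised)
OTHER = "OTHER"

PATTERN_BASE = "tRNA_ORF1_TrpRSA1"
PATTERN_PLUS_BACT = "tRNA_ORF1_TrpRSA1_plus_bacterialTrpRS"
PATTERN_TRPR = "trpR_headed"
PATTERN_A2_CLUSTER = "archaeal_cluster_A2"

_LINEAGE_ROLE = {
    "TrpRS_A1": TRPRS_A1,
    "TrpRS_A2": TRPRS_A2,
    "TrpRS_A_like": TRPRS_ALIKE,
}


@dataclass
class LocusConfig:
    max_gap: int = 150          # nt between adjacent operon members
    cluster_gap: int = 1000     # nt between co-localised archaeal-cluster members
    orf1_min_len: int = 120     # residues
    orf1_max_len: int = 450


@dataclass
class GenomicFeature:
    id: str
    contig: str
    start: int        # 1-based inclusive
    end: int
    strand: str
    kind: str         # tRNA / CDS
    name: str = ""    # template / Name attribute
    genome: str = ""
    sequence: str = ""          # coding-strand nucleotides
    protein: Optional[str] = None
    call: object = None         # IdentityCall or AarsTypeCall
    motif_hits: list = field(default_factory=list)
    role: str = OTHER
    warnings: list = field(default_factory=list)


@dataclass
class OperonCall:
    contig: str
    strand: str
    pattern: str
    member_ids: tuple
    max_internal_gap: int

    def key(self) -> tuple:
        return (self.contig, self.pattern, self.member_ids)


@dataclass
class GenomeIdentitySummary:
    genome: str
    trna_counts: dict      # (isotype, domain_type) -> n
    aars_counts: dict      # lineage -> n
    dual_identity: bool


# ------------------------------------------------------------------ grammar

def match_patterns(roles: Sequence[str], starts: Sequence[int],
                   ends: Sequence[int], max_gap: int = 150,
                   cluster_gap: int = 1000) -> list[tuple[str, tuple, int]]:
    """Locus grammar over transcription-ordered role labels.

    ``starts``/``ends`` are transcription-order coordinates (monotone along
    the list). Returns (pattern, member-index tuple, max internal gap);
    overlapping patterns are each reported.
    """
    n = len(roles)
    assert n == len(starts) == len(ends)
    gaps = [starts[i + 1] - ends[i] - 1 for i in range(n - 1)]
    out: list[tuple[str, tuple, int]] = []

    def window_ok(i: int, j: int) -> bool:
        return all(g <= max_gap for g in gaps[i:j])

    def maxgap(i: int, j: int) -> int:
        return max(gaps[i:j]) if j > i else 0

    strict = [
        (PATTERN_BASE, (TRNA_TRP_A, ORF1, TRPRS_A1)),
        (PATTERN_PLUS_BACT, (TRNA_TRP_A, ORF1, TRPRS_A1, TRPRS_BACT)),
        (PATTERN_TRPR, (TRPR, TRNA_TRP_A, ORF1, TRPRS_A1)),
    ]
    for pat, seq in strict:
        k = len(seq)
        for i in range(n - k + 1):
            if tuple(roles[i:i + k]) == seq and window_ok(i, i + k - 1):
                out.append((pat, tuple(range(i, i + k)), maxgap(i, i + k - 1)))

    cluster_roles = {TRNA_TRP_A, ORF1, TRPRS_A2, TRPRS_ALIKE}
    members = [i for i, r in enumerate(roles) if r in cluster_roles]
    run: list[int] = []
    runs: list[list[int]] = []
    for idx in members:
        if run and starts[idx] - ends[run[-1]] - 1 > cluster_gap:
            runs.append(run)
            run = []
        run.append(idx)
    if run:
        runs.append(run)
    for run in runs:
        rset = {roles[i] for i in run}
        if TRNA_TRP_A in rset and ORF1 in rset and rset & {TRPRS_A2, TRPRS_ALIKE}:
            gap = max((starts[b] - ends[a] - 1 for a, b in zip(run, run[1:])),
                      default=0)
            out.append((PATTERN_A2_CLUSTER, tuple(run), gap))
    return out


# ------------------------------------------------------------------ features

def load_features(gff_rows: Sequence[dict], contigs: dict[str, str],
                  genome_of: Optional[dict[str, str]] = None) -> list[GenomicFeature]:
    """Build strand-corrected features from parsed GFF3 rows + contig FASTA."""
    feats = []
    for row in gff_rows:
        contig = row["seqid"]
        if contig not in contigs:
            raise ValueError(
                f"line {row.get('line', '?')}: feature references unknown "
                f"contig {contig!r}")
        start, end = row["start"], row["end"]
        if not (1 <= start <= end <= len(contigs[contig])):
            raise ValueError(
                f"line {row.get('line', '?')}: span {start}..{end} outside "
                f"contig {contig!r} (length {len(contigs[contig])})")
        seq = contigs[contig][start - 1:end]
        if row["strand"] == "-":
            seq = revcomp(seq)
        attrs = row.get("attributes", {})
        genome = attrs.get("genome") or (genome_of or {}).get(contig, contig)
        feats.append(GenomicFeature(
            id=attrs.get("ID", f"{contig}:{start}-{end}"),
            contig=contig, start=start, end=end, strand=row["strand"],
            kind=row["type"], name=attrs.get("Name", ""), genome=genome,
            sequence=seq,
        ))
    return feats


def _translate(dna: str) -> str:
    from Bio.Seq import Seq
    prot = str(Seq(dna).translate(to_stop=True))
    return prot[1:] if prot.startswith("M") else prot


def annotate_features(features: Sequence[GenomicFeature],
                      refs: Sequence[A.Reference],
                      cls_cfg: Optional[A.ClassifierConfig] = None,
                      locus_cfg: Optional[LocusConfig] = None) -> list[GenomicFeature]:
    """Attach identity/type calls and roles; then flag ORF1 candidates."""
    cls_cfg = cls_cfg or A.ClassifierConfig()
    locus_cfg = locus_cfg or LocusConfig()
    for f in features:
        if f.kind == "tRNA":
            _annotate_trna(f)
        elif f.kind == "CDS":
            _annotate_cds(f, refs, cls_cfg)
    call_orf1_candidates(features, locus_cfg)
    return list(features)


def _annotate_trna(f: GenomicFeature) -> None:
    try:
        cl = C.fold_cloverleaf(f.sequence)
    except ValueError as exc:
        f.warnings.append(f"fold precondition: {exc}")
        return
    if not cl.foldable:
        f.warnings.append(f"unfoldable: {cl.reason}")
        return
    profile = C.extract_identity_profile(cl)
    try:
        call = C.classify_identity(profile)
    except ValueError as exc:
        f.warnings.append(str(exc))
        return
    f.call = call
    if call.isotype == "Trp":
        f.role = (TRNA_TRP_A if call.domain_type == C.DOMAIN_ARCHAEAL
                  else TRNA_TRP_BACT if call.domain_type == C.DOMAIN_BACTERIAL
                  else OTHER)
    else:
        f.role = TRNA_TYR


def _annotate_cds(f: GenomicFeature, refs: Sequence[A.Reference],
                  cfg: A.ClassifierConfig) -> None:
    f.protein = _translate(f.sequence)
    if not f.protein:
        f.warnings.append("empty translation")
        return
    f.motif_hits = A.scan_class_i_motifs(f.protein) + A.scan_fes_motif(f.protein)
    if f.name == "trp_repressor":
        f.role = TRPR
        return
    if refs:
        f.call = A.classify_aars(f.protein, refs, cfg)
        if f.call.lineage in _LINEAGE_ROLE:
            f.role = _LINEAGE_ROLE[f.call.lineage]
        elif f.call.family == "TrpRS" and f.call.lineage == "bacteria_type":
            f.role = TRPRS_BACT


def call_orf1_candidates(features: Sequence[GenomicFeature],
                         cfg: Optional[LocusConfig] = None) -> list[GenomicFeature]:
    """Flag unassigned CDSs as ORF1 when position, no-similarity and
    motif-content conditions all hold (conjunction of the three)."""
    cfg = cfg or LocusConfig()
    flagged = []
    for contig, strand, ordered in _iter_transcription_units(features):
        tstarts, tends = _transcription_coords(ordered)
        for i, f in enumerate(ordered):
            if f.kind != "CDS" or f.call is None:
                continue
            if f.call.lineage != "unassigned":
                continue
            if f.protein is None or not (
                    cfg.orf1_min_len <= len(f.protein) <= cfg.orf1_max_len):
                continue
            names = {h.motif_name for h in f.motif_hits}
            if not {"HIGH", "KMSKS"} <= names:
                continue
            if not _orf1_position_ok(ordered, tstarts, tends, i, cfg):
                continue
            f.role = ORF1
            flagged.append(f)
    return flagged


def _orf1_position_ok(ordered, tstarts, tends, i, cfg: LocusConfig) -> bool:
    prev_ok = (i > 0 and ordered[i - 1].role == TRNA_TRP_A
               and tstarts[i] - tends[i - 1] - 1 <= cfg.max_gap)
    next_ok = (i + 1 < len(ordered)
               and ordered[i + 1].role in (TRPRS_A1, TRPRS_A2, TRPRS_ALIKE)
               and tstarts[i + 1] - tends[i] - 1 <= cfg.max_gap)
    if prev_ok and next_ok:
        return True
    # archaeal-cluster context: co-localised with an A2/A-like gene
    for j, g in enumerate(ordered):
        if g.role in (TRPRS_A2, TRPRS_ALIKE):
            dist = (tstarts[i] - tends[j] - 1 if j < i
                    else tstarts[j] - tends[i] - 1)
            if dist <= cfg.cluster_gap:
                return True
    return False


# ------------------------------------------------------------------ operons

def _iter_transcription_units(features):
    keys = sorted({(f.contig, f.strand) for f in features})
    for contig, strand in keys:
        unit = [f for f in features if f.contig == contig and f.strand == strand]
        unit.sort(key=lambda f: f.start)
        if strand == "-":
            unit.reverse()
        yield contig, strand, unit


def _transcription_coords(ordered):
    starts, ends = [], []
    for f in ordered:
        if f.strand == "-":
            starts.append(-f.end)
            ends.append(-f.start)
        else:
            starts.append(f.start)
            ends.append(f.end)
    return starts, ends


def detect_operons(features: Sequence[GenomicFeature],
                   cfg: Optional[LocusConfig] = None) -> list[OperonCall]:
    """Detect all locus patterns per contig/strand in transcription order."""
    cfg = cfg or LocusConfig()
    calls = []
    for contig, strand, ordered in _iter_transcription_units(features):
        starts, ends = _transcription_coords(ordered)
        roles = [f.role for f in ordered]
        for pattern, idxs, gap in match_patterns(
                roles, starts, ends, cfg.max_gap, cfg.cluster_gap):
            calls.append(OperonCall(
                contig=contig, strand=strand, pattern=pattern,
                member_ids=tuple(ordered[i].id for i in idxs),
                max_internal_gap=gap))
    calls.sort(key=lambda c: (c.contig, c.pattern, c.member_ids))
    return calls


# ------------------------------------------------------------------ summaries

def summarize_genome(features: Sequence[GenomicFeature]) -> dict[str, GenomeIdentitySummary]:
    """Per-genome tRNA identity inventory, aaRS lineage inventory,
    dual-identity flag (both a bacterial and an archaeal/eukaryal tRNA call
    for the same isotype)."""
    out: dict[str, GenomeIdentitySummary] = {}
    for genome in sorted({f.genome for f in features}):
        fs = [f for f in features if f.genome == genome]
        trna_counts: dict = {}
        aars_counts: dict = {}
        for f in fs:
            if f.kind == "tRNA" and isinstance(f.call, C.IdentityCall):
                key = (f.call.isotype, f.call.domain_type)
                trna_counts[key] = trna_counts.get(key, 0) + 1
            elif f.kind == "CDS" and isinstance(f.call, A.AarsTypeCall):
                lin = "ORF1_like" if f.role == ORF1 else f.call.lineage
                aars_counts[lin] = aars_counts.get(lin, 0) + 1
        dual = any(
            (iso, C.DOMAIN_BACTERIAL) in trna_counts
            and (iso, C.DOMAIN_ARCHAEAL) in trna_counts
            for iso in ("Tyr", "Trp"))
        out[genome] = GenomeIdentitySummary(genome, trna_counts, aars_counts, dual)
    return out
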