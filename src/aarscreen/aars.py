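"""aaRS candidate annotation: class I motifs, Fe-S motif, similarity typing.

Class Ic aminoacyl-tRNA synthetases (TyrRS/TrpRS) carry the HIGH and KMSKS
catalytic motifs of class I aaRSs; the non-canonical TrpRS-A2 clade adds a
four-cysteine C-x22-C-x6-C-x2-C motif predicted to chelate a [4Fe-4S]
cluster. Candidate proteins are typed by nearest labelled reference under a
BLAST-like "positives" similarity (global affine alignment, BLOSUM62,
positives / aligned columns with terminal gaps excluded), mirroring the
>=40%-similarity collection rule used to assemble the families.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# degenerate class I motif patterns: one allowed-letter set per position.
HIGH_PATTERN = ("HNQ", "ILVMAFG", "G", "HN")
KMSKS_PATTERN = ("KR", "MLIVF", "S", "KS", "SG")
# Fe-S motif spacing: C, 22 any, C, 6 any, C, 2 any, C  (34-residue span)
FES_SPACERS = (22, 6, 2)
FES_SPAN = 4 + sum(FES_SPACERS)

LINEAGES = ("bacteria_type", "archaea_eukarya_type", "TrpRS_A1", "TrpRS_A2",
            "TrpRS_A_like", "ORF1_like", "unassigned")


@dataclass
class MotifHit:
    motif_name: str          # HIGH / KMSKS / FeS_C4
    start: int               # 1-based inclusive
    end: int                 # 1-based inclusive
    matched_text: str
    pattern_id: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Segment:
    name: str
    start: int   # 1-based inclusive
    end: int
    evidence: str = ""


@dataclass
class DomainArchitecture:
    segments: list[Segment] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def segment(self, name: str) -> Optional[Segment]:
        for s in self.segments:
            if s.name == name:
                return s
        return None

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.segments]


@dataclass
class Reference:
    id: str
    family: str    # TyrRS / TrpRS / other
    lineage: str
    sequence: str


@dataclass
class ClassifierConfig:
    similarity_threshold: float = 0.40
    require_fes_for_a2: bool = False
    full_length: bool = False   # denominator includes terminal gaps when True

    def __post_init__(self):
        if not 0 < self.similarity_threshold <= 1:
            raise ValueError("similarity_threshold must be in (0, 1]")


@dataclass
class AarsTypeCall:
    family: str
    lineage: str
    best_reference: Optional[str]
    similarity: float
    evidence: list  # top references as (id, lineage, similarity)


@dataclass
class BreakpointReport:
    window: int
    step: int
    track: list          # (alignment column of window centre, identity)
    breakpoints: list    # residue positions in sequence a (1-based)
    n_breakpoints: int


# ------------------------------------------------------------------ motifs

def _pattern_regex(pattern: Sequence[str]) -> str:
    return "".join(p if len(p) == 1 else f"[{p}]" for p in pattern)


def _check_alphabet(protein: str) -> str:
    protein = protein.upper()
    bad = set(protein) - set(AA20 + "X")
    if bad:
        raise ValueError(f"bad amino-acid characters: {sorted(bad)}")
    return protein


def scan_class_i_motifs(protein: str,
                        high_pattern: Sequence[str] = HIGH_PATTERN,
                        kmsks_pattern: Sequence[str] = KMSKS_PATTERN) -> list[MotifHit]:
    """All non-overlapping HIGH and KMSKS matches, greedy left-to-right."""
    protein = _check_alphabet(protein)
    hits: list[MotifHit] = []
    for name, pat in (("HIGH", high_pattern), ("KMSKS", kmsks_pattern)):
        rx = re.compile(_pattern_regex(pat))
        for m in rx.finditer(protein):
            hits.append(MotifHit(name, m.start() + 1, m.end(),
                                 m.group(0), pattern_id=_pattern_regex(pat)))
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


def scan_fes_motif(protein: str) -> list[MotifHit]:
    """All (possibly overlapping) C-x22-C-x6-C-x2-C matches."""
    protein = _check_alphabet(protein)
    rx = re.compile(r"(?=(C.{22}C.{6}C.{2}C))", re.DOTALL)
    hits = []
    for m in rx.finditer(protein):
        s = m.start() + 1
        hits.append(MotifHit("FeS_C4", s, s + FES_SPAN - 1, m.group(1),
                             pattern_id="C-x22-C-x6-C-x2-C"))
    return hits


def audit_trp_content(protein: str) -> tuple[int, bool]:
    """Count tryptophans; flag tryptophan-free proteins."""
    protein = _check_alphabet(protein)
    count = protein.count("W")
    return count, count == 0


# ------------------------------------------------------------------ alignment

@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _aligned_strings(a: str, b: str) -> tuple[str, str]:
    aln = _aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _trim_terminal_gaps(ga: str, gb: str) -> tuple[str, str, int]:
    i, j = 0, len(ga)
    while i < j and (ga[i] == "-" or gb[i] == "-"):
        i += 1
    while j > i and (ga[j - 1] == "-" or gb[j - 1] == "-"):
        j -= 1
    return ga[i:j], gb[i:j], i


@dataclass
class AlignmentStats:
    similarity: float       # positives fraction
    identity: float
    columns: int            # denominator actually used
    aligned_columns: int    # columns after terminal-gap trimming


def alignment_stats(a: str, b: str, full_length: bool = False) -> AlignmentStats:
    """Global-alignment positives/identity fractions for a protein pair.

    Symmetric by construction: the pair is ordered canonically before
    alignment. ``full_length`` switches the denominator to the full
    alignment length (terminal gaps included).
    """
    a, b = _check_alphabet(a), _check_alphabet(b)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    swap = b < a
    ga, gb = _aligned_strings(*( (b, a) if swap else (a, b) ))
    ta, tb, _ = _trim_terminal_gaps(ga, gb)
    mat = substitution_matrices.load("BLOSUM62")
    positives = ident = 0
    for x, y in zip(ta, tb):
        if x != "-" and y != "-":
            if mat[x][y] > 0:
                positives += 1
            if x == y:
                ident += 1
    denom = len(ga) if full_length else len(ta)
    denom = max(denom, 1)
    return AlignmentStats(similarity=positives / denom, identity=ident / denom,
                          columns=denom, aligned_columns=len(ta))


def pairwise_similarity(a: str, b: str, full_length: bool = False) -> float:
    """BLAST-style positives fraction from a global affine BLOSUM62 alignment."""
    return alignment_stats(a, b, full_length=full_length).similarity


# ------------------------------------------------------------------ typing

def classify_aars(protein: str, refs: Sequence[Reference],
                  cfg: Optional[ClassifierConfig] = None) -> AarsTypeCall:
    """Nearest-reference family/lineage typing with a similarity floor."""
    if not refs:
        raise ValueError("reference set is empty (configuration error)")
    cfg = cfg or ClassifierConfig()
    protein = _check_alphabet(protein)
    scored = []
    for ref in refs:
        sim = pairwise_similarity(protein, ref.sequence,
                                  full_length=cfg.full_length)
        scored.append((ref, sim))
    scored.sort(key=lambda t: (-t[1], t[0].id))
    top, top_sim = scored[0]
    evidence = [(r.id, r.lineage, round(s, 4)) for r, s in scored[:3]]
    if top_sim < cfg.similarity_threshold:
        return AarsTypeCall("unknown", "unassigned", None, top_sim, evidence)
    family, lineage = top.family, top.lineage
    if cfg.require_fes_for_a2 and lineage == "TrpRS_A2":
        if not scan_fes_motif(protein):
            evidence.append(("FeS_C4", "required-but-absent", 0.0))
            return AarsTypeCall(family, "unassigned", top.id, top_sim, evidence)
    return AarsTypeCall(family, lineage, top.id, top_sim, evidence)


# ------------------------------------------------------------------ architecture

@dataclass
class ArchitectureRefs:
    b2: Optional[str] = None
    s4: Optional[str] = None
    similarity_threshold: float = 0.40


def detect_architecture(protein: str,
                        refs: Optional[ArchitectureRefs] = None) -> DomainArchitecture:
    """Segment a class Ic aaRS into B2 / linker / catalytic core / ABD / S4-like.

    The catalytic core spans HIGH..KMSKS; an N-terminal B2 domain (the OB-fold
    RNA-binding domain of bacterial PheRS beta) and a C-terminal S4-like
    domain (the V-arm-binding domain of bacteria-type TyrRS) are called by
    similarity to user-supplied reference domains.
    """
    refs = refs or ArchitectureRefs()
    protein = _check_alphabet(protein)
    arch = DomainArchitecture()
    hits = scan_class_i_motifs(protein)
    highs = [h for h in hits if h.motif_name == "HIGH"]
    if not highs:
        arch.warnings.append("no HIGH motif: catalytic core not located")
        return arch
    high = highs[0]
    kmsks = next((h for h in hits
                  if h.motif_name == "KMSKS" and h.start > high.end), None)

    core_end = kmsks.end if kmsks else len(protein)
    nterm = protein[:high.start - 1]

    b2_end = 0
    if refs.b2 and len(nterm) >= 20:
        b2_len = min(len(nterm), len(refs.b2))
        sim = pairwise_similarity(nterm[:b2_len], refs.b2)
        if sim >= refs.similarity_threshold:
            b2_end = b2_len
            arch.segments.append(Segment("B2", 1, b2_end,
                                         evidence=f"similarity {sim:.2f} to B2 reference"))
    if b2_end and high.start - 1 - b2_end >= 10:
        arch.segments.append(Segment("linker", b2_end + 1, high.start - 1,
                                     evidence="inter-domain region between B2 and core"))

    arch.segments.append(Segment(
        "catalytic_core", high.start, core_end,
        evidence=f"HIGH {high.start}-{high.end}" +
                 (f", KMSKS {kmsks.start}-{kmsks.end}" if kmsks else ", KMSKS absent")))
    if not kmsks:
        arch.warnings.append("no KMSKS motif downstream of HIGH; core extended to C-terminus")
        return arch

    s4_start = 0
    if refs.s4 and len(protein) - core_end >= len(refs.s4) // 2:
        s4_len = min(len(protein) - core_end, len(refs.s4))
        tail = protein[len(protein) - s4_len:]
        sim = pairwise_similarity(tail, refs.s4)
        if sim >= refs.similarity_threshold:
            s4_start = len(protein) - s4_len + 1
            abd_end = s4_start - 1
        else:
            abd_end = len(protein)
    else:
        abd_end = len(protein)

    if abd_end > core_end:
        arch.segments.append(Segment("ABD", core_end + 1, abd_end,
                                     evidence="anticodon-binding region after KMSKS"))
    if s4_start:
        arch.segments.append(Segment("S4_like", s4_start, len(protein),
                                     evidence="C-terminal similarity to S4 reference"))
    return arch


# ------------------------------------------------------------------ breakpoints

def detect_breakpoints(a: str, b: str, window: int = 30, step: int = 10,
                       high_thr: float = 0.9, low_thr: float = 0.5) -> BreakpointReport:
    """Sliding-window identity track over a global alignment, with
    plateau-transition breakpoints.

    A breakpoint is reported wherever the track crosses from a >= high_thr
    plateau to a <= low_thr plateau (or back), the signature of a domain-swap
    junction between two otherwise near-identical genes.
    """
    if window < 10:
        raise ValueError("window must be >= 10")
    if not high_thr > low_thr:
        raise ValueError("high_thr must exceed low_thr")
    a, b = _check_alphabet(a), _check_alphabet(b)
    ga, gb = _aligned_strings(a, b)
    ta, tb, offset = _trim_terminal_gaps(ga, gb)
    n = len(ta)
    if n < window:
        raise ValueError(f"aligned region ({n} columns) too short for window {window}")

    # residue index in `a` at each trimmed-alignment column (1-based, cumulative)
    a_res = []
    count = sum(1 for c in ga[:offset] if c != "-")
    for c in ta:
        if c != "-":
            count += 1
        a_res.append(count)

    track = []
    states = []   # +1 high, -1 low, 0 mid per window
    for start in range(0, n - window + 1, step):
        wa, wb = ta[start:start + window], tb[start:start + window]
        ident = sum(1 for x, y in zip(wa, wb) if x == y and x != "-") / window
        centre = start + window // 2
        track.append((centre, ident))
        states.append(1 if ident >= high_thr else (-1 if ident <= low_thr else 0))

    breakpoints = []
    last_state = 0
    last_centre = None
    for (centre, _), st in zip(track, states):
        if st == 0:
            continue
        if last_state != 0 and st != last_state:
            mid_col = (last_centre + centre) // 2
            breakpoints.append(a_res[mid_col])
        last_state, last_centre = st, centre

    return BreakpointReport(window=window, step=step, track=track,
                            breakpoints=breakpoints,
                            n_breakpoints=len(breakpoints))
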