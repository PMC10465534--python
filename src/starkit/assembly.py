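"""In-silico Golden-Gate-style assembly of regulatory RNA arrays.

Parts carry 4-nt fusion overhangs; adjacent parts must agree at every
junction and share the scar once in the assembled sequence.  The assembly
report includes a forbidden-site scan (both strands, IUPAC-aware) and a
direct-repeat statistic relevant to recombination-driven instability of
tandem arrays.

Coordinates are 0-based half-open throughout.

The default part sequences are editable placeholders with valid overhang
chemistry, not validated biological sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AssemblyError, ParameterError

__all__ = [
    "Part",
    "Junction",
    "SiteHit",
    "RepeatReport",
    "AssemblyReport",
    "DEFAULT_PARTS",
    "TYPE_IIS_SITES",
    "assemble_array",
    "scan_forbidden_sites",
    "repeat_risk",
    "load_parts_fasta",
    "write_fasta",
]

_DNA_RE = re.compile(r"^[ACGT]+$")
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Recognition sites of Type IIS enzymes commonly excluded from part interiors.
TYPE_IIS_SITES = {"BsaI": "GGTCTC", "BsmBI": "CGTCTC", "BbsI": "GAAGAC"}

PART_CATEGORIES = ("STAR", "insulator", "promoter", "target")


@dataclass(frozen=True)
class Part:
    """A cloning part: uppercase DNA with 4-nt fusion overhangs at both ends.

    The stored sequence includes both overhangs; ``upstream`` must equal the
    first 4 nt and ``downstream`` the last 4 nt.
    """

    id: str
    category: str
    sequence: str
    upstream: str
    downstream: str

    def __post_init__(self):
        if self.category not in PART_CATEGORIES:
            raise ParameterError("category", f"{self.category!r} not in {PART_CATEGORIES}")
        if not self.sequence or not _DNA_RE.match(self.sequence):
            raise ParameterError("sequence", "must be non-empty uppercase DNA over ACGT")
        for name in ("upstream", "downstream"):
            oh = getattr(self, name)
            if len(oh) != 4 or not _DNA_RE.match(oh):
                raise ParameterError(name, f"overhang must be 4 nt of ACGT, got {oh!r}")
        if len(self.sequence) < 8:
            raise ParameterError("sequence", "part must be at least 8 nt (two overhangs)")
        if self.sequence[:4] != self.upstream:
            raise ParameterError("upstream", "overhang does not match sequence start")
        if self.sequence[-4:] != self.downstream:
            raise ParameterError("downstream", "overhang does not match sequence end")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Junction:
    """One fusion site between adjacent parts in an assembly."""

    position: int  # start of the shared 4-nt scar in the assembled sequence
    left_part: str
    right_part: str
    overhang: str
    ok: bool


@dataclass(frozen=True)
class SiteHit:
    """One enzyme-site occurrence; ``strand`` is '+' or '-'."""

    enzyme: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class RepeatReport:
    """Direct-repeat statistics of a sequence.

    ``length``/``positions`` describe the longest exact repeat occurring at
    least twice without overlap; ``unit_length``/``unit_copies`` its smallest
    tandem period and how many non-overlapping copies of that unit the full
    sequence holds.  ``score = length * copies`` summarizes instability risk.
    """

    length: int
    positions: tuple[int, ...]
    copies: int
    unit_length: int
    unit_copies: int
    score: int


@dataclass(frozen=True)
class AssemblyReport:
    sequence: str
    parts: tuple[str, ...]
    junctions: tuple[Junction, ...]
    forbidden_sites: tuple[SiteHit, ...]
    repeats: RepeatReport

    @property
    def length(self) -> int:
        return len(self.sequence)


def _expand_iupac(site: str) -> re.Pattern:
    out = []
    for c in site.upper():
        if c not in _IUPAC:
            raise ParameterError("site", f"invalid IUPAC code {c!r} in {site!r}")
        chars = _IUPAC[c]
        out.append(chars if len(chars) == 1 else f"[{chars}]")
    # Lookahead so overlapping occurrences are all reported.
    return re.compile(f"(?=({''.join(out)}))")


def scan_forbidden_sites(seq: str, enzymes: dict[str, str] | None = None) -> list[SiteHit]:
    """All occurrences of each recognition site on both strands.

    Coordinates are 0-based half-open on the forward sequence.  A
    palindromic site matches at the same locus on both strands; such hits
    are deduplicated to a single '+' entry.
    """
    if enzymes is None:
        enzymes = TYPE_IIS_SITES
    seq = seq.upper()
    hits: list[SiteHit] = []
    for name, site in enzymes.items():
        pat = _expand_iupac(site)
        rc = str(Seq(site).reverse_complement())
        pat_rc = _expand_iupac(rc)
        fwd = {m.start() for m in pat.finditer(seq)}
        for start in sorted(fwd):
            hits.append(SiteHit(name, start, start + len(site), "+"))
        for m in pat_rc.finditer(seq):
            if m.start() in fwd and rc == site.upper():
                continue  # palindromic: already reported on '+'
            hits.append(SiteHit(name, m.start(), m.start() + len(site), "-"))
    return sorted(hits, key=lambda h: (h.start, h.enzyme, h.strand))


def _longest_nonoverlapping_repeat(seq: str) -> tuple[int, tuple[int, ...]]:
    """Longest substring occurring >= 2 times without overlap.

    Binary search on length; candidate lengths checked with a k-mer position
    index (first and last occurrence span >= k implies a non-overlapping pair).
    """
    n = len(seq)
    best_len, best_pos = 0, ()

    def check(k: int) -> tuple[int, ...] | None:
        first: dict[str, int] = {}
        for i in range(n - k + 1):
            kmer = seq[i:i + k]
            j = first.setdefault(kmer, i)
            if i - j >= k:
                return (j, i)
        return None

    lo, hi = 1, n // 2
    while lo <= hi:
        mid = (lo + hi) // 2
        pos = check(mid)
        if pos is not None:
            best_len, best_pos = mid, pos
            lo = mid + 1
        else:
            hi = mid - 1
    return best_len, best_pos


def _smallest_period(s: str) -> int:
    """Smallest p such that s is a whole number of repeats of s[:p]
    (falls back to len(s) when s is primitive)."""
    n = len(s)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    p = n - fail[-1]
    return p if n % p == 0 else n


def _count_nonoverlapping(seq: str, sub: str) -> int:
    count = start = 0
    while True:
        i = seq.find(sub, start)
        if i < 0:
            return count
        count += 1
        start = i + len(sub)


def repeat_risk(seq: str) -> RepeatReport:
    """Direct-repeat report for recombination-instability screening.

    For a clean k-fold tandem array the longest repeat is half the repeated
    region; its smallest period recovers the repeat unit, and ``unit_copies``
    counts the tandem copies (k for a k-fold array).
    """
    seq = seq.upper()
    if len(seq) < 2:
        return RepeatReport(length=0, positions=(), copies=0,
                            unit_length=0, unit_copies=0, score=0)
    length, positions = _longest_nonoverlapping_repeat(seq)
    if length == 0:
        return RepeatReport(length=0, positions=(), copies=0,
                            unit_length=0, unit_copies=0, score=0)
    rep = seq[positions[0]:positions[0] + length]
    copies = _count_nonoverlapping(seq, rep)
    unit_len = _smallest_period(rep)
    unit = rep[:unit_len]
    unit_copies = _count_nonoverlapping(seq, unit)
    return RepeatReport(length=length, positions=positions, copies=copies,
                        unit_length=unit_len, unit_copies=unit_copies,
                        score=length * copies)


def _join(parts: Sequence[Part]) -> tuple[str, tuple[Junction, ...]]:
    pieces = [parts[0].sequence]
    junctions = []
    offset = len(parts[0].sequence)
    for left, right in zip(parts, parts[1:]):
        ok = left.downstream == right.upstream
        junctions.append(Junction(
            position=offset - 4, left_part=left.id, right_part=right.id,
            overhang=left.downstream, ok=ok,
        ))
        if not ok:
            raise AssemblyError(
                f"overhang mismatch at junction {left.id}->{right.id}: "
                f"{left.downstream} vs {right.upstream}"
            )
        pieces.append(right.sequence[4:])  # shared scar kept once
        offset += len(right.sequence) - 4
    return "".join(pieces), tuple(junctions)


def assemble_array(
    star: Part,
    insulator: Part,
    copies: int = 1,
    order: Sequence[Part] | None = None,
    enzymes: dict[str, str] | None = None,
) -> AssemblyReport:
    """Assemble a regulatory RNA array: each activator part followed by its
    insulator, repeated ``copies`` times (or following an explicit mixed
    ``order`` of activator parts for multiplex arrays).

    Assembled length = sum of part lengths minus one shared 4-nt scar per
    junction.  Raises on out-of-range copies or any overhang mismatch.
    """
    if order is not None:
        stars = list(order)
        copies = len(stars)
    else:
        stars = [star] * copies
    if not 1 <= copies <= 8:
        raise ParameterError("copies", f"must be in [1, 8], got {copies}")
    blocks: list[Part] = []
    for s in stars:
        blocks.extend([s, insulator])
    sequence, junctions = _join(blocks)
    return AssemblyReport(
        sequence=sequence,
        parts=tuple(p.id for p in blocks),
        junctions=junctions,
        forbidden_sites=tuple(scan_forbidden_sites(sequence, enzymes)),
        repeats=repeat_risk(sequence),
    )


# ---------------------------------------------------------------------------
# FASTA I/O: parts annotated via ``key=value`` tokens in the description,
# e.g. ">STAR50 category=STAR uo=AATG do=GCTT".
# ---------------------------------------------------------------------------

def load_parts_fasta(path: str | Path) -> dict[str, Part]:
    parts: dict[str, Part] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        tags = dict(
            token.split("=", 1) for token in record.description.split()[1:] if "=" in token
        )
        seq = str(record.seq).upper()
        parts[record.id] = Part(
            id=record.id,
            category=tags.get("category", "STAR"),
            sequence=seq,
            upstream=tags.get("uo", seq[:4]),
            downstream=tags.get("do", seq[-4:]),
        )
    if not parts:
        raise AssemblyError(f"no FASTA records found in {path}")
    return parts


def write_fasta(path: str | Path, name: str, sequence: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i:i + 70] + "\n")


def _placeholder(seed_text: str, length: int, upstream: str, downstream: str) -> str:
    """Deterministic filler DNA between fixed overhangs (placeholder parts)."""
    import hashlib

    body_len = length - 8
    out = []
    counter = 0
    while len(out) < body_len:
        digest = hashlib.sha256(f"{seed_text}:{counter}".encode()).digest()
        out.extend("ACGT"[b % 4] for b in digest)
        counter += 1
    return upstream + "".join(out[:body_len]) + downstream


#: Placeholder part set with consistent overhang chemistry: STAR parts run
#: AATG...GCTT, insulators GCTT...AATG, so STAR-insulator blocks chain.
DEFAULT_PARTS: dict[str, Part] = {
    "STAR10": Part("STAR10", "STAR", _placeholder("STAR10", 100, "AATG", "GCTT"), "AATG", "GCTT"),
    "STAR50": Part("STAR50", "STAR", _placeholder("STAR50", 100, "AATG", "GCTT"), "AATG", "GCTT"),
    "PlmJ": Part("PlmJ", "insulator", _placeholder("PlmJ", 60, "GCTT", "AATG"), "GCTT", "AATG"),
    "csy4hp": Part("csy4hp", "insulator", _placeholder("csy4hp", 28, "GCTT", "AATG"), "GCTT", "AATG"),
    "shcsy4hp": Part("shcsy4hp", "insulator", _placeholder("shcsy4hp", 48, "GCTT", "AATG"), "GCTT", "AATG"),
}
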