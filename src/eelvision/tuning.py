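"""Spectral-tuning-site annotation in bovine rhodopsin numbering.

Opsin residues are conventionally numbered by alignment to the bovine
rod opsin precursor (348 aa, 1-based including the initiator Met).
This module aligns a query opsin to that reference, reads off the
residues at the registered tuning sites of its opsin class, calls
substitutions against the class consensus, and annotates substitutions
with known spectral-shift rules (e.g. S292A → 7–16 nm red shift).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "SiteRegistry",
    "NumberingMap",
    "SiteCall",
    "SiteReport",
    "ShiftRule",
    "REGISTRIES",
    "SHIFT_RULES",
    "load_reference",
    "build_numbering_map",
    "extract_sites",
    "annotate_shifts",
]

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SiteRegistry:
    """Registered tuning sites for one opsin class.

    ``consensus`` maps known sites to the class consensus residue used
    for substitution calls; putative sites are reported but carry no
    consensus, hence no call.
    """

    opsin_class: str
    consensus: dict[int, str]  # known sites → consensus residue
    putative: tuple[int, ...] = ()

    @property
    def known_sites(self) -> tuple[int, ...]:
        return tuple(sorted(self.consensus))

    @property
    def sites(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.consensus) | set(self.putative)))

    def status(self, site: int) -> str:
        return "known" if site in self.consensus else "putative"


#: Class registries.  Known-site consensus residues follow the standard
#: freshwater-eel comparisons; Rh1 putative sites comprise the four
#: retinal-pocket candidates (124, 189, 286, 290) and the eight sites
#: whose residue interactions diverge between eel Rh1f pigments.
REGISTRIES: dict[str, SiteRegistry] = {
    "Rh1": SiteRegistry(
        "Rh1",
        consensus={83: "D", 122: "E", 207: "M", 211: "H", 265: "W",
                   292: "S", 295: "A"},
        putative=(112, 124, 137, 189, 191, 193, 219, 255, 286, 290, 313),
    ),
    "Rh2": SiteRegistry(
        "Rh2",
        consensus={97: "T", 122: "E", 207: "M", 292: "S"},
    ),
    "SWS2": SiteRegistry(
        "SWS2",
        consensus={94: "A", 116: "M", 118: "T", 265: "W", 292: "S"},
    ),
}


@dataclass(frozen=True)
class ShiftRule:
    """Documented λ_max shift for one substitution."""

    site: int
    from_residue: str
    to_residue: str
    direction: str  # "blue" | "red"
    magnitude_nm: tuple[float, float] | None  # None = unspecified

    @property
    def substitution(self) -> str:
        return f"{self.from_residue}{self.site}{self.to_residue}"


#: Shift rules with experimental support in vertebrate rod opsins.
SHIFT_RULES: tuple[ShiftRule, ...] = (
    ShiftRule(292, "S", "A", "red", (7.0, 16.0)),
    ShiftRule(292, "A", "S", "blue", (7.0, 15.0)),
    ShiftRule(83, "D", "N", "blue", None),
)


@dataclass(frozen=True)
class NumberingMap:
    """Monotone query-position → reference-position map (both 1-based)."""

    query_id: str
    query_to_ref: dict[int, int]
    score: float
    identity: float
    low_identity: bool = False

    def __post_init__(self) -> None:
        qs = sorted(self.query_to_ref)
        rs = [self.query_to_ref[q] for q in qs]
        if any(b <= a for a, b in zip(rs, rs[1:])):
            raise ValueError("numbering map is not strictly increasing")
        object.__setattr__(
            self, "ref_to_query", {r: q for q, r in self.query_to_ref.items()}
        )


@dataclass(frozen=True)
class SiteCall:
    site: int
    status: str  # known | putative
    query_residue: str  # one-letter or "-" for gap
    consensus_residue: str | None
    substitution: str | None  # e.g. "S292A"
    shift_direction: str | None = None
    shift_magnitude_nm: tuple[float, float] | None = None
    shift_note: str | None = None


@dataclass(frozen=True)
class SiteReport:
    query_id: str
    opsin_class: str
    calls: tuple[SiteCall, ...] = field(default_factory=tuple)

    @property
    def substitutions(self) -> tuple[str, ...]:
        return tuple(c.substitution for c in self.calls if c.substitution)


def load_reference() -> str:
    """Bovine rhodopsin reference sequence shipped with the package."""
    with resources.files("eelvision.data").joinpath(
        "bovine_rhodopsin.fasta"
    ).open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return str(record.seq)


def _make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = -11.0, gap_extend: float = -1.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aligner.mode = "global"
    # do not penalise terminal gaps: opsin C-termini vary in length
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.88
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def build_numbering_map(
    query: str,
    reference: str | None = None,
    query_id: str = "query",
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    identity_floor: float = 0.30,
) -> NumberingMap:
    """Align a query opsin to the reference and build a position map.

    Global pairwise alignment with an affine gap penalty; aligned
    (non-gap) columns become 1-based query→reference position pairs.
    An alignment identity below ``identity_floor`` sets a warning flag
    rather than raising.
    """
    if reference is None:
        reference = load_reference()
    query = query.upper().replace("*", "")
    if not (200 <= len(query) <= 600):
        raise ValueError(f"query length {len(query)} outside 200–600 residues")
    bad = set(query) - AA_LETTERS
    if bad:
        raise ValueError(f"non-standard residues in query: {sorted(bad)}")

    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(reference, query)[0]
    ref_blocks, query_blocks = alignment.aligned

    pairs: dict[int, int] = {}
    matches = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, query_blocks):
        for offset in range(re_ - rs):
            rpos, qpos = rs + offset, qs + offset
            pairs[qpos + 1] = rpos + 1
            if reference[rpos] == query[qpos]:
                matches += 1
    identity = matches / max(len(reference), len(query))
    return NumberingMap(
        query_id=query_id,
        query_to_ref=pairs,
        score=float(alignment.score),
        identity=identity,
        low_identity=identity < identity_floor,
    )


def extract_sites(
    nmap: NumberingMap,
    query: str,
    registry: SiteRegistry | str,
) -> SiteReport:
    """Report the query residues at every registered site.

    Sites absent from the alignment (deleted in the query) are reported
    as gaps.  Substitutions are called against the class consensus for
    known sites only.
    """
    if isinstance(registry, str):
        registry = REGISTRIES[registry]
    query = query.upper()
    ref_to_query = nmap.ref_to_query  # set in __post_init__
    calls = []
    for site in registry.sites:
        qpos = ref_to_query.get(site)
        residue = query[qpos - 1] if qpos is not None else "-"
        consensus = registry.consensus.get(site)
        substitution = None
        if consensus is not None and residue not in ("-", consensus):
            substitution = f"{consensus}{site}{residue}"
        calls.append(
            SiteCall(
                site=site,
                status=registry.status(site),
                query_residue=residue,
                consensus_residue=consensus,
                substitution=substitution,
            )
        )
    return SiteReport(nmap.query_id, registry.opsin_class, tuple(calls))


def annotate_shifts(
    report: SiteReport, rules: tuple[ShiftRule, ...] = SHIFT_RULES
) -> SiteReport:
    """Attach shift direction/magnitude to substitution calls.

    Calls with no matching rule are annotated "no rule"; calls without a
    substitution are left untouched.
    """
    by_sub = {r.substitution: r for r in rules}
    annotated = []
    for call in report.calls:
        if call.substitution is None:
            annotated.append(call)
            continue
        rule = by_sub.get(call.substitution)
        if rule is None:
            annotated.append(
                SiteCall(
                    **{**call.__dict__, "shift_note": "no rule"},
                )
            )
        else:
            annotated.append(
                SiteCall(
                    **{
                        **call.__dict__,
                        "shift_direction": rule.direction,
                        "shift_magnitude_nm": rule.magnitude_nm,
                        "shift_note": None
                        if rule.magnitude_nm
                        else "magnitude unspecified",
                    },
                )
            )
    return SiteReport(report.query_id, report.opsin_class, tuple(annotated))
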