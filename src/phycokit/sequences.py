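"""Catalogue of mature phycobiliprotein alpha subunits.

Cryptophyte antenna alpha subunits are nuclear-encoded precursors carrying an
N-terminal targeting peptide.  The mature protein is recognised by the
conserved ``AP-x(9-10)-C`` motif around the chromophore-binding cysteine and is
released by cleavage after an ``A-x-A`` site at the end of the targeting
peptide.  Quaternary form follows from two insertions relative to the closed
form: a single residue (canonically Asp) immediately before the chromophore
Cys produces the *open* form, and an additional ~7-residue *L1* loop between
strand S2 and helix H1 "braces" the open form (*open-braced*).

This module turns candidate transcript translations into a deduplicated
catalogue of mature subunits with form class and theoretical average mass.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.SeqUtils import molecular_weight

__all__ = [
    "AlphaCandidate",
    "MatureAlphaSubunit",
    "ReferenceFrame",
    "ALPHA_MOTIF",
    "PEB_MASS_DA",
    "MET_OX_MASS_DA",
    "default_reference_frame",
    "filter_by_alpha_motif",
    "cleave_mature",
    "deduplicate_across_strains",
    "classify_form",
    "compute_mature_mass",
    "build_catalog",
    "read_candidates_fasta",
    "write_catalog",
]

log = logging.getLogger(__name__)

#: Conserved alpha-subunit motif: Ala-Pro, a 9- or 10-residue spacer, then the
#: chromophore-binding Cys.  A 10-residue spacer marks the open-form insertion.
ALPHA_MOTIF = re.compile(r"AP(.{9,10})C")

#: Average mass of one phycoerythrobilin chromophore (Da).
PEB_MASS_DA = 586.7
#: Average mass increment of one methionine oxidation (Da).
MET_OX_MASS_DA = 16.0

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass(frozen=True)
class AlphaCandidate:
    """A candidate alpha-subunit translation, prior to maturation."""

    id: str
    strain: str
    sequence: str
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")


@dataclass
class MatureAlphaSubunit:
    """A matured alpha subunit with provenance back to its precursor."""

    id: str
    strain: str
    mature_sequence: str
    precursor: str
    cleavage_site_index: int
    n_term_extension: int = 0
    c_term_extension: int = 0
    form_class: str = "unclassified"
    theoretical_mass: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.precursor[self.cleavage_site_index:] != self.mature_sequence:
            raise ValueError(
                f"{self.id}: mature sequence is not the precursor suffix at "
                f"index {self.cleavage_site_index}"
            )


@dataclass(frozen=True)
class ReferenceFrame:
    """Reference mature alpha subunit with annotated motif columns.

    The reference is a closed-form mature sequence; all column indices are
    0-based positions in it.  ``open_insertion_column`` is the spacer column
    immediately preceding ``chromophore_cys_column``: the one-residue open-form
    insertion lands between the two.  ``s2_h1_gap_span`` is the half-open
    column interval between strand S2 and helix H1 where the L1 loop inserts.
    """

    reference_mature: str
    chromophore_cys_column: int
    open_insertion_column: int
    s2_h1_gap_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.open_insertion_column != self.chromophore_cys_column - 1:
            raise ValueError("open insertion column must immediately precede the Cys column")
        if self.reference_mature[self.chromophore_cys_column] != "C":
            raise ValueError("chromophore column is not a Cys in the reference")


# Synthetic closed-form reference scaffold.  Designed, not a database entry:
# single Cys, single AP, no internal A-x-A site, length in the 55-67 residue
# range of natural mature alpha subunits.
_REFERENCE_MATURE = (
    "AP" + "MSRTVDNLK" + "C" + "DGKQFETLG" + "VNSLNGDLTR" + "EVMKQFDEMS" + "GKSGDY" + "TTLEHWKR"
)


def default_reference_frame() -> ReferenceFrame:
    """The packaged (synthetic) reference frame used throughout the package."""
    return ReferenceFrame(
        reference_mature=_REFERENCE_MATURE,
        chromophore_cys_column=11,
        open_insertion_column=10,
        s2_h1_gap_span=(18, 26),
    )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # free end gaps: precursors and tails overhang the mature frame
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def _clean(seq: str) -> str:
    return seq.rstrip("*")


# ---------------------------------------------------------------------------
# motif filter


def filter_by_alpha_motif(candidates: list[AlphaCandidate]) -> list[AlphaCandidate]:
    """Keep candidates containing the AP-x(9-10)-C motif, preserving order."""
    if not candidates:
        log.warning("filter_by_alpha_motif: empty candidate list")
        return []
    return [c for c in candidates if ALPHA_MOTIF.search(_clean(c.sequence))]


# ---------------------------------------------------------------------------
# maturation


def _axa_sites(seq: str) -> list[int]:
    """0-based start indices of A-x-A sites (overlapping allowed)."""
    return [m.start() for m in re.finditer(r"(?=A.A)", seq)]


def cleave_mature(
    candidate: AlphaCandidate,
    frame: ReferenceFrame | None = None,
    override_site: int | None = None,
) -> MatureAlphaSubunit:
    """Cleave a precursor after the second Ala of its A-x-A site.

    When several sites exist, the one whose mature N-terminus carries the
    fewest extension residues ahead of the reference frame start is chosen
    (preferring non-negative extensions, i.e. cleavage at or before the motif).
    Sequences with no A-x-A site are returned in full and flagged
    ``no_AxA_site``; a known non-canonical site (e.g. the one SFS site called
    by an external targeting predictor) can be supplied via ``override_site``.
    """
    frame = frame or default_reference_frame()
    seq = _clean(candidate.sequence)
    if len(seq) < 3:
        raise ValueError(f"{candidate.id}: sequence shorter than 3 residues")

    flags: set[str] = set()
    if "X" in seq:
        flags.add("ambiguous_residues")

    motif = ALPHA_MOTIF.search(seq)
    motif_start = motif.start() if motif else None

    if override_site is not None:
        cut = override_site
    else:
        sites = [s + 3 for s in _axa_sites(seq)]  # mature start indices
        sites = [s for s in sites if s < len(seq)]
        if not sites:
            flags.add("no_AxA_site")
            cut = 0
        elif motif_start is None:
            cut = sites[0]
        else:
            # extension = residues between cleavage and the frame start
            nonneg = [s for s in sites if motif_start - s >= 0]
            cut = max(nonneg) if nonneg else min(sites)

    mature = seq[cut:]
    n_ext, c_ext = _extensions(mature, frame)
    sub = MatureAlphaSubunit(
        id=candidate.id,
        strain=candidate.strain,
        mature_sequence=mature,
        precursor=seq,
        cleavage_site_index=cut,
        n_term_extension=n_ext,
        c_term_extension=c_ext,
        flags=flags,
    )
    if "X" not in mature:
        sub.theoretical_mass = compute_mature_mass(mature)
    return sub


def _extensions(mature: str, frame: ReferenceFrame) -> tuple[int, int]:
    """Residues overhanging the reference frame at either terminus."""
    aln = _ALIGNER.align(frame.reference_mature, mature)[0]
    blocks = aln.aligned
    if len(blocks[0]) == 0:
        return 0, 0
    first_q = int(blocks[1][0][0])
    last_q = int(blocks[1][-1][1])
    first_t = int(blocks[0][0][0])
    # overhang beyond the frame start only (not internal gap slack)
    n_ext = max(0, first_q - first_t)
    c_ext = max(0, (len(mature) - last_q) - (len(frame.reference_mature) - int(blocks[0][-1][1])))
    return n_ext, c_ext


# ---------------------------------------------------------------------------
# deduplication


def _x_compatible_contains(longer: str, shorter: str) -> bool:
    """True if ``shorter`` matches a contiguous window of ``longer`` with X wildcards."""
    n, m = len(longer), len(shorter)
    for off in range(n - m + 1):
        if all(a == b or a == "X" or b == "X" for a, b in zip(longer[off:off + m], shorter)):
            return True
    return False


def _same_group(a: str, b: str) -> bool:
    if len(a) < len(b):
        a, b = b, a
    return _x_compatible_contains(a, b)


def deduplicate_across_strains(subunits: list[MatureAlphaSubunit]) -> list[MatureAlphaSubunit]:
    """Collapse cross-strain duplicates, keeping the most complete read.

    Mature regions identical up to X-ambiguity and truncation are grouped; the
    longest read wins, ties broken by fewest X then lexicographically smallest
    id.  Tandem reads (two concatenated motifs) are flagged ``tandem_read`` and
    excluded from grouping.
    """
    kept: list[MatureAlphaSubunit] = []
    singles: list[MatureAlphaSubunit] = []
    for sub in subunits:
        if len(ALPHA_MOTIF.findall(sub.mature_sequence)) >= 2:
            sub.flags.add("tandem_read")
        else:
            singles.append(sub)

    # union-find over pairwise compatibility
    parent = list(range(len(singles)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(singles)):
        for j in range(i + 1, len(singles)):
            if _same_group(singles[i].mature_sequence, singles[j].mature_sequence):
                parent[find(i)] = find(j)

    groups: dict[int, list[MatureAlphaSubunit]] = {}
    for i, sub in enumerate(singles):
        groups.setdefault(find(i), []).append(sub)

    for members in groups.values():
        best = min(
            members,
            key=lambda s: (-len(s.mature_sequence), s.mature_sequence.count("X"), s.id),
        )
        kept.append(best)
    kept.sort(key=lambda s: s.id)
    return kept


# ---------------------------------------------------------------------------
# form classification


def classify_form(
    subunit: MatureAlphaSubunit,
    frame: ReferenceFrame | None = None,
    braced_window: tuple[int, int] = (5, 8),
    min_score_ratio: float = 0.4,
) -> str:
    """Classify the quaternary form of a mature subunit.

    ``open`` iff a one-residue insertion occupies the spacer column
    immediately before the chromophore Cys (equivalently: a 10-residue motif
    spacer).  ``open_braced`` iff open *and* an insertion of ``braced_window``
    residues falls in the S2-H1 gap span.  ``closed`` iff neither insertion.
    ``unclassified`` when no chromophore Cys aligns or the alignment score is
    below ``min_score_ratio`` of the reference self-score.
    """
    frame = frame or default_reference_frame()
    seq = subunit.mature_sequence
    motif = ALPHA_MOTIF.search(seq)
    if motif is None:
        log.warning("%s: no chromophore Cys motif alignable; unclassified", subunit.id)
        return "unclassified"

    ref = frame.reference_mature
    aln = _ALIGNER.align(ref, seq)[0]
    self_score = _ALIGNER.score(ref, ref)
    if aln.score < min_score_ratio * self_score:
        return "unclassified"

    is_open = len(motif.group(1)) == 10

    # query insertions relative to the reference: gaps in the target between
    # consecutive aligned blocks
    braced = False
    tblocks, qblocks = aln.aligned
    lo, hi = frame.s2_h1_gap_span
    for k in range(1, len(tblocks)):
        t_gap = int(tblocks[k][0]) - int(tblocks[k - 1][1])
        q_gap = int(qblocks[k][0]) - int(qblocks[k - 1][1])
        ins_len = q_gap - t_gap
        ref_pos = int(tblocks[k][0])
        if ins_len >= braced_window[0] and ins_len <= braced_window[1] and lo <= ref_pos <= hi:
            braced = True

    if is_open and braced:
        return "open_braced"
    if is_open:
        return "open"
    return "closed"


# ---------------------------------------------------------------------------
# mass


def compute_mature_mass(
    subunit: MatureAlphaSubunit | str,
    n_bilins: int = 0,
    n_met_ox: int = 0,
) -> float:
    """Theoretical average mass (Da) of a mature subunit.

    Average peptide mass (residues + one water) plus 586.7 Da per bilin and a
    16 Da ladder per methionine oxidation.  Ambiguous residues are an error.
    """
    seq = subunit if isinstance(subunit, str) else subunit.mature_sequence
    if "X" in seq:
        pos = [i for i, r in enumerate(seq) if r == "X"]
        raise ValueError(f"ambiguous residues at positions {pos}; no mass computable")
    peptide = molecular_weight(seq, seq_type="protein", monoisotopic=False)
    return peptide + PEB_MASS_DA * n_bilins + MET_OX_MASS_DA * n_met_ox


# ---------------------------------------------------------------------------
# pipeline + IO


def build_catalog(
    candidates: list[AlphaCandidate],
    frame: ReferenceFrame | None = None,
    braced_window: tuple[int, int] = (5, 8),
) -> list[MatureAlphaSubunit]:
    """Full catalogue pipeline: motif filter, cleave, deduplicate, classify."""
    frame = frame or default_reference_frame()
    retained = filter_by_alpha_motif(candidates)
    matured = [cleave_mature(c, frame) for c in retained]
    unique = deduplicate_across_strains(matured)
    out = []
    for sub in unique:
        out.append(replace_form(sub, classify_form(sub, frame, braced_window)))
    return out


def replace_form(sub: MatureAlphaSubunit, form: str) -> MatureAlphaSubunit:
    sub.form_class = form
    return sub


def read_candidates_fasta(path) -> list[AlphaCandidate]:
    """Read candidates from FASTA; record ids carry strain tags as ``id|strain``."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ident, _, strain = rec.id.partition("|")
        out.append(
            AlphaCandidate(
                id=ident, strain=strain or "unknown",
                sequence=str(rec.seq), source_note=rec.description,
            )
        )
    return out


def write_catalog(subunits: list[MatureAlphaSubunit], tsv_path, fasta_path=None) -> None:
    """Write the catalogue as TSV (and, optionally, the mature sequences as FASTA)."""
    import pandas as pd

    rows = []
    for s in subunits:
        rows.append(
            {
                "id": s.id,
                "strain": s.strain,
                "form_class": s.form_class,
                "cleavage_site_index": s.cleavage_site_index,
                "n_term_extension": s.n_term_extension,
                "c_term_extension": s.c_term_extension,
                "theoretical_mass_da": (
                    round(s.theoretical_mass, 2) if s.theoretical_mass else ""
                ),
                "flags": ",".join(sorted(s.flags)),
            }
        )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for s in subunits:
                fh.write(f">{s.id}|{s.strain} form={s.form_class}\n{s.mature_sequence}\n")
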