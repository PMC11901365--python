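"""Chothia position assignment, CDR extraction and fixed-grid padding.

The numbering backend aligns a query variable-domain sequence to a packaged
germline-like template whose residues cover every base Chothia label, maps
framework residues through the template columns, and renumbers each CDR
window with the scheme's insertion rule (fill forward to the insertion
point, the window tail is anchored at its last labels, surplus residues
receive insertion letters on the sanctioned position).

Canonical grids: heavy = 132 slots, light = 122 slots.  The slot lists are
shipped as data files; base positions are the Chothia numbers (82A-C fixed
on the heavy chain) and the insertion slots are 31A-B / 52A-C / 100A-K
(heavy) and 30A-F / 52A-B / 95A-F / 106A (light).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import GridOverflow, MissingRegion, UnnumberableSequence

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")
INSERTION_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

_LABEL_RE = re.compile(r"^([HL])(\d+)([A-Z]?)$")


def label_key(label: str) -> tuple[int, int]:
    """Sort key for a position label in Chothia order (insertions follow base)."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"malformed position label: {label!r}")
    _, num, letter = m.groups()
    return int(num), (0 if not letter else INSERTION_LETTERS.index(letter) + 1)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ChainSequence:
    """A raw variable-domain chain: id, heavy/light flag, residue string."""

    id: str
    chain_type: str  # "heavy" | "light"
    residues: str

    def __post_init__(self):
        if self.chain_type not in ("heavy", "light"):
            raise ValueError(f"chain_type must be heavy/light, got {self.chain_type!r}")
        if not self.residues:
            raise UnnumberableSequence("bad-alphabet", "empty sequence")
        bad = set(self.residues) - VALID_AA
        if bad:
            raise UnnumberableSequence(
                "bad-alphabet", f"{self.id}: invalid residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class NumberedChain:
    """Ordered (position label, residue) assignments for one chain."""

    chain_type: str
    assignments: tuple[tuple[str, str], ...]

    @property
    def residues(self) -> str:
        return "".join(res for _, res in self.assignments)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass(frozen=True)
class GridSpec:
    """Fixed slot list a chain is padded onto, plus the encoder pad character."""

    chain_type: str
    positions: tuple[str, ...]
    pad_char: str = "_"

    @property
    def slot_count(self) -> int:
        return len(self.positions)

    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.positions)}


@dataclass(frozen=True)
class PaddedChainPair:
    """Both chains of one antibody on their canonical grids."""

    heavy_padded: str
    light_padded: str
    heavy_id: str = ""
    light_id: str = ""
    pad_char: str = "_"


# CDR windows as inclusive (start, end) label pairs per loop name.
_CDR_TABLES = {
    "kabat": {
        "H1": ("H31", "H35"), "H2": ("H50", "H58"), "H3": ("H95", "H102"),
        "L1": ("L24", "L34"), "L2": ("L50", "L56"), "L3": ("L89", "L97"),
    },
    "chothia": {
        "H1": ("H26", "H32"), "H2": ("H52", "H56"), "H3": ("H95", "H102"),
        "L1": ("L24", "L34"), "L2": ("L50", "L56"), "L3": ("L89", "L97"),
    },
    "kabat_chothia_martin": {
        "H1": ("H26", "H35"), "H2": ("H50", "H58"), "H3": ("H95", "H102"),
        "L1": ("L24", "L34"), "L2": ("L50", "L56"), "L3": ("L89", "L97"),
    },
}


@dataclass(frozen=True)
class CDRDefinition:
    """Named CDR definition; H3 is fixed at H95-H102 in every definition."""

    name: str = "kabat_chothia_martin"
    windows: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in _CDR_TABLES:
            raise ValueError(f"unknown CDR definition {self.name!r}")
        if not self.windows:
            object.__setattr__(self, "windows", dict(_CDR_TABLES[self.name]))
        for start, end in self.windows.values():
            if label_key(start) > label_key(end):
                raise ValueError(f"CDR window reversed: {start}..{end}")


# ---------------------------------------------------------------------------
# packaged references

# Template segment layout.  Each segment is (n_residues, labels) where the
# framework segments map 1:1 onto base labels and CDR segments declare the
# renumbering window (start, end, insertion point).
_HEAVY_SEGMENTS = (
    ("fr", 25, "H1", "H25"),
    ("cdr", 7, "H26", "H32", "H31"),
    ("fr", 17, "H33", "H49"),
    ("cdr", 9, "H50", "H58", "H52"),
    ("fr", 48 - 9, "H59", "H94"),   # includes fixed 82A-C
    ("cdr", 8, "H95", "H102", "H100"),
    ("fr", 11, "H103", "H113"),
)
_LIGHT_SEGMENTS = (
    ("fr", 23, "L1", "L23"),
    ("cdr", 11, "L24", "L34", "L30"),
    ("fr", 15, "L35", "L49"),
    ("cdr", 7, "L50", "L56", "L52"),
    ("fr", 32, "L57", "L88"),
    ("cdr", 9, "L89", "L97", "L95"),
    ("fr", 10, "L98", "L107"),
)

# Conserved anchors checked after numbering (label -> required residue).
_ANCHORS = {"heavy": {"H22": "C", "H92": "C"}, "light": {"L23": "C", "L88": "C"}}


def _read_data_text(name: str) -> str:
    return resources.files("abtriage.data").joinpath(name).read_text()


@lru_cache(maxsize=None)
def load_grid(chain_type: str, pad_char: str = "_") -> GridSpec:
    """Load the canonical 132-slot heavy or 122-slot light grid."""
    fname = {"heavy": "chothia_heavy_grid.txt", "light": "chothia_light_grid.txt"}[chain_type]
    labels = tuple(
        line.strip() for line in _read_data_text(fname).splitlines()
        if line.strip() and not line.startswith("#")
    )
    expected = 132 if chain_type == "heavy" else 122
    if len(labels) != expected:
        raise RuntimeError(f"{fname}: expected {expected} slots, found {len(labels)}")
    return GridSpec(chain_type=chain_type, positions=labels, pad_char=pad_char)


@lru_cache(maxsize=None)
def _reference_sequences() -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    for line in _read_data_text("reference_chains.fasta").splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name:
            seqs[name] += line.strip()
    return seqs


def _base_labels(chain_type: str) -> tuple[str, ...]:
    """Base labels = grid labels minus pure insertion slots (82A-C kept)."""
    grid = load_grid(chain_type)
    ins_slots = {
        "heavy": {"H31A", "H31B", "H52A", "H52B", "H52C"}
        | {f"H100{c}" for c in "ABCDEFGHIJK"},
        "light": {f"L30{c}" for c in "ABCDEF"} | {"L52A", "L52B"}
        | {f"L95{c}" for c in "ABCDEF"} | {"L106A"},
    }[chain_type]
    return tuple(lab for lab in grid.positions if lab not in ins_slots)


@lru_cache(maxsize=None)
def _template(chain_type: str, which: str = "heavy_consensus"):
    """Template residues with their base-label assignment and segment map."""
    seq = _reference_sequences()[which]
    labels = _base_labels(chain_type)
    if len(seq) != len(labels):
        raise RuntimeError(f"template {which} length {len(seq)} != {len(labels)} base labels")
    segments = _HEAVY_SEGMENTS if chain_type == "heavy" else _LIGHT_SEGMENTS
    # map template residue index -> (segment id, label)
    seg_of: list[int] = []
    for si, seg in enumerate(segments):
        seg_of.extend([si] * seg[1])
    return seq, labels, segments, tuple(seg_of)


@lru_cache(maxsize=None)
def _window_columns(chain_type: str, template_name: str) -> frozenset:
    tpl, _, segments, seg_of = _template(chain_type, template_name)
    return frozenset(i for i in range(len(tpl)) if segments[seg_of[i]][0] == "cdr")


@lru_cache(maxsize=None)
def _fast_aligner() -> Align.PairwiseAligner:
    """Affine-gap global aligner (fast path; used for most chains)."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    if hasattr(aligner, "open_end_insertion_score"):
        aligner.open_end_insertion_score = -5.0
        aligner.extend_end_insertion_score = -0.5
        aligner.open_end_deletion_score = -5.0
        aligner.extend_end_deletion_score = -0.5
    else:  # Biopython < 1.86 attribute names
        aligner.target_end_open_gap_score = -5.0
        aligner.target_end_extend_gap_score = -0.5
        aligner.query_end_open_gap_score = -5.0
        aligner.query_end_extend_gap_score = -0.5
    return aligner


def _make_aligner(chain_type: str, template_name: str,
                  query_len: int) -> Align.PairwiseAligner:
    """Global aligner with position-dependent gap scores: template-side gaps
    (query insertions) are cheap inside CDR windows and expensive inside
    frameworks, so length variation is forced onto the sanctioned loops.
    Callable gap scores put Biopython on its slow generic path, so this is
    only the fallback when the affine aligner misplaces an insertion."""
    tpl_len = len(_template(chain_type, template_name)[0])
    win_cols = _window_columns(chain_type, template_name)

    def template_gap(start, length):
        if start in win_cols or (start - 1) in win_cols:
            return -1.0 - 0.1 * (length - 1)
        if start in (0, tpl_len):
            return -5.0 - 0.5 * (length - 1)
        return -11.0 - 1.0 * (length - 1)

    def query_gap(start, length):
        if start in (0, query_len):
            return -5.0 - 0.5 * (length - 1)
        return -11.0 - 1.0 * (length - 1)

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    if hasattr(aligner, "insertion_score"):
        aligner.insertion_score = template_gap
        aligner.deletion_score = query_gap
    else:  # Biopython < 1.86 attribute names
        aligner.target_gap_score = template_gap
        aligner.query_gap_score = query_gap
    return aligner


def _window_labels(start: str, end: str, ins_point: str, n: int) -> list[str]:
    """Assign n residues to the inclusive window [start, end] with insertions
    at ins_point.  The tail labels after the insertion point are anchored at
    the window end; surplus residues get letters on the insertion point."""
    chain = start[0]
    s, e, p = label_key(start)[0], label_key(end)[0], label_key(ins_point)[0]
    forward = [f"{chain}{i}" for i in range(s, p + 1)]
    tail = [f"{chain}{i}" for i in range(p + 1, e + 1)]
    n_tail = min(n, len(tail))
    tail_labels = tail[len(tail) - n_tail:]
    r = n - n_tail
    if r <= len(forward):
        head_labels = forward[:r]
        ins_labels: list[str] = []
    else:
        head_labels = forward
        n_ins = r - len(forward)
        if n_ins > len(INSERTION_LETTERS):
            raise UnnumberableSequence(
                "too-many-insertions", f"{n_ins} insertions at {ins_point}"
            )
        ins_labels = [f"{ins_point}{INSERTION_LETTERS[i]}" for i in range(n_ins)]
    return head_labels + ins_labels + tail_labels


def _align_and_number(chain: ChainSequence, template_name: str) -> NumberedChain:
    try:
        aln = _fast_aligner().align(
            _template(chain.chain_type, template_name)[0], chain.residues)[0]
        return _number_from_alignment(chain, template_name, aln)
    except UnnumberableSequence as exc:
        if exc.reason != "framework-insertion":
            raise
    aligner = _make_aligner(chain.chain_type, template_name, len(chain.residues))
    aln = aligner.align(_template(chain.chain_type, template_name)[0],
                        chain.residues)[0]
    return _number_from_alignment(chain, template_name, aln)


def _number_from_alignment(chain: ChainSequence, template_name: str,
                           aln) -> NumberedChain:
    tpl_seq, tpl_labels, segments, seg_of = _template(chain.chain_type, template_name)
    # items: (segment id or None, template index or None, query residue)
    items: list[tuple[int | None, int | None, str]] = []
    t_blocks, q_blocks = aln.aligned
    t_prev, q_prev = 0, 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        # Unaligned query residues before this block are insertions.  At a
        # framework/CDR boundary they belong to the CDR window; only an
        # insertion strictly interior to a framework segment is fatal.
        for qi in range(q_prev, qs):
            before = seg_of[t_prev - 1] if t_prev > 0 else None
            after = seg_of[ts] if ts < len(seg_of) else None
            candidates = [s for s in (before, after) if s is not None]
            cdr_candidates = [s for s in candidates if segments[s][0] == "cdr"]
            items.append(((cdr_candidates or candidates)[0], None, chain.residues[qi]))
        for ti, qi in zip(range(ts, te), range(qs, qe)):
            items.append((seg_of[ti], ti, chain.residues[qi]))
        t_prev, q_prev = te, qe
    for qi in range(q_prev, len(chain.residues)):
        items.append((seg_of[-1], None, chain.residues[qi]))

    assignments: list[tuple[str, str]] = []
    i = 0
    while i < len(items):
        si = items[i][0]
        seg = segments[si]
        j = i
        while j < len(items) and items[j][0] == si:
            j += 1
        run = items[i:j]
        if seg[0] == "fr":
            for s_id, ti, res in run:
                if ti is None:
                    raise UnnumberableSequence(
                        "framework-insertion",
                        f"{chain.id}: insertion in framework near {seg[2]}",
                    )
                assignments.append((tpl_labels[ti], res))
        else:
            _, _, start, end, ins_point = seg
            labels = _window_labels(start, end, ins_point, len(run))
            assignments.extend(zip(labels, (res for _, _, res in run)))
        i = j
    return NumberedChain(chain_type=chain.chain_type, assignments=tuple(assignments))


# ---------------------------------------------------------------------------
# operations


def number_chain(chain: ChainSequence) -> NumberedChain:
    """Assign Chothia position labels to every residue of a chain.

    Raises :class:`UnnumberableSequence` when the alphabet, length or
    conserved cysteine anchors rule the sequence out; callers drop the
    record and report the reason.
    """
    n = len(chain.residues)
    if not 70 <= n <= 150:
        raise UnnumberableSequence("length-out-of-range", f"{chain.id}: length {n}")
    if chain.chain_type == "heavy":
        numbered = _align_and_number(chain, "heavy_consensus")
    else:
        best = None
        for tpl in ("kappa_consensus", "lambda_consensus"):
            try:
                cand = _align_and_number(chain, tpl)
            except UnnumberableSequence:
                continue
            score = _framework_identity(cand, tpl)
            if best is None or score > best[0]:
                best = (score, cand)
        if best is None:
            raise UnnumberableSequence("missing-anchor", f"{chain.id}: no template fits")
        numbered = best[1]
    got = dict(numbered.assignments)
    for lab, want in _ANCHORS[chain.chain_type].items():
        if got.get(lab) != want:
            raise UnnumberableSequence(
                "missing-anchor", f"{chain.id}: {want} expected at {lab}"
            )
    if numbered.residues != chain.residues:
        raise UnnumberableSequence("missing-anchor", f"{chain.id}: round-trip failed")
    return numbered


def pad_to_grid(numbered: NumberedChain, grid: GridSpec) -> str:
    """Place residues on the fixed grid; empty slots hold the pad character."""
    if numbered.chain_type != grid.chain_type:
        raise GridOverflow(f"{numbered.chain_type} chain on {grid.chain_type} grid")
    index = grid.index()
    slots = [grid.pad_char] * grid.slot_count
    for lab, res in numbered.assignments:
        if lab not in index:
            raise GridOverflow(f"label {lab} outside canonical grid")
        slots[index[lab]] = res
    return "".join(slots)


def extract_cdr(numbered: NumberedChain, cdr: CDRDefinition, loop: str) -> str:
    """Residues whose labels fall in the loop's inclusive window, grid order."""
    if loop not in cdr.windows:
        raise MissingRegion(f"unknown loop {loop!r}")
    if loop[0] != ("H" if numbered.chain_type == "heavy" else "L"):
        raise MissingRegion(f"{loop} requested on a {numbered.chain_type} chain")
    start, end = cdr.windows[loop]
    lo, hi = label_key(start), label_key(end)
    sub = "".join(res for lab, res in numbered.assignments if lo <= label_key(lab) <= hi)
    if not sub:
        raise MissingRegion(f"no residues in {loop} window {start}..{end}")
    return sub


def _framework_identity(numbered: NumberedChain, reference_name: str) -> float:
    """Ungapped identity over framework labels shared with a reference chain."""
    ref_seq, ref_labels, segments, seg_of = _template(numbered.chain_type, reference_name)
    fr_label_to_res = {
        ref_labels[i]: ref_seq[i]
        for i in range(len(ref_seq))
        if segments[seg_of[i]][0] == "fr"
    }
    shared = [(lab, res) for lab, res in numbered.assignments if lab in fr_label_to_res]
    if not shared:
        return 0.0
    same = sum(1 for lab, res in shared if fr_label_to_res[lab] == res)
    return same / len(shared)


def classify_light_chain(light: ChainSequence) -> str:
    """Type a light chain as kappa or lambda by framework identity to the
    packaged references; ties go to kappa."""
    if light.chain_type != "light":
        raise ValueError("classify_light_chain expects a light chain")
    numbered = number_chain(light)
    kappa = _framework_identity(numbered, "kappa_consensus")
    lam = _framework_identity(numbered, "lambda_consensus")
    return "kappa" if kappa >= lam else "lambda"


def reference_chain(name: str) -> ChainSequence:
    """Packaged reference as a ChainSequence (heavy_consensus, kappa_consensus,
    lambda_consensus)."""
    chain_type = "heavy" if name.startswith("heavy") else "light"
    return ChainSequence(id=name, chain_type=chain_type,
                         residues=_reference_sequences()[name])
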