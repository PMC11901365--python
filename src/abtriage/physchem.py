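"""Sequence-only physicochemical calculators and the Z-score pre-filter.

Implements the additive per-residue unfolding free-energy model, the
iterative Henderson-Hasselbalch isoelectric-point solver (EMBOSS pKa set,
seeded at pH 6.5, charge tolerance 0.01), CDR-H3 length on the H95-H102
window, the more-than-two-cysteines hard rule, reference statistics, the
Z-gate, and a two-tailed Mann-Whitney comparison.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInput,
    InsufficientData,
    MissingRegion,
    NonConvergence,
    UnknownResidue,
)
from .numbering import ChainSequence, NumberedChain, CDRDefinition, label_key

PCF_FEATURES = ("cdr_h3_length", "dg_vh", "dg_vl", "dg_concat", "mean_pi")


# ---------------------------------------------------------------------------
# parameter tables


@dataclass(frozen=True)
class ThermoTables:
    """Per-residue unfolding enthalpy (kJ/mol) and entropy (kJ/mol/K)."""

    dH: dict
    dS: dict
    temperature: float = 298.15

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.dH) | (
            set("ACDEFGHIKLMNPQRSTVWY") - set(self.dS)
        )
        if missing:
            raise ValueError(f"thermo table missing residues: {sorted(missing)}")

    @classmethod
    def from_csv(cls, text: str, temperature: float = 298.15) -> "ThermoTables":
        rows = [r for r in csv.DictReader(
            io.StringIO("\n".join(l for l in text.splitlines() if not l.startswith("#")))
        )]
        dH = {r["residue"]: float(r["dH_kJ_mol"]) for r in rows}
        dS = {r["residue"]: float(r["dS_kJ_mol_K"]) for r in rows}
        return cls(dH=dH, dS=dS, temperature=temperature)

    @classmethod
    def packaged(cls, temperature: float = 298.15) -> "ThermoTables":
        return _packaged_thermo(temperature)


@lru_cache(maxsize=None)
def _packaged_thermo(temperature: float) -> ThermoTables:
    text = resources.files("abtriage.data").joinpath("oobatake_thermo.csv").read_text()
    return ThermoTables.from_csv(text, temperature=temperature)


@dataclass(frozen=True)
class PIParams:
    """pKa set and solver controls for the isoelectric-point calculation."""

    pka: dict = field(default_factory=lambda: dict(_packaged_pka()))
    start_ph: float = 6.5
    tolerance: float = 0.01
    max_iterations: int = 200

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        for group, value in self.pka.items():
            if not 0 < value < 14:
                raise ValueError(f"pKa out of range for {group}: {value}")


@lru_cache(maxsize=None)
def _packaged_pka() -> tuple[tuple[str, float], ...]:
    text = resources.files("abtriage.data").joinpath("pka_emboss.csv").read_text()
    rows = csv.DictReader(
        io.StringIO("\n".join(l for l in text.splitlines() if not l.startswith("#")))
    )
    return tuple((r["group"], float(r["pka"])) for r in rows)


# ---------------------------------------------------------------------------
# calculators


def cdr_h3_length(heavy: NumberedChain) -> int:
    """Residue count in the inclusive H95-H102 window, insertions included."""
    if heavy.chain_type != "heavy":
        raise MissingRegion("CDR-H3 requested on a light chain")
    lo, hi = label_key("H95"), label_key("H102")
    n = sum(1 for lab, _ in heavy.assignments if lo <= label_key(lab) <= hi)
    if n == 0:
        raise MissingRegion("no residues in H95-H102 window")
    return n


def cysteine_filter(chain: ChainSequence) -> tuple[bool, int]:
    """(passes, cysteine count); more than two cysteines fails the chain."""
    count = chain.residues.count("C")
    return count <= 2, count


def delta_g_unfolding(seq: str, tables: ThermoTables | None = None) -> float:
    """Additive unfolding free energy: sum over residues of dH_i - T*dS_i."""
    tables = tables or ThermoTables.packaged()
    total = 0.0
    for aa in seq:
        try:
            total += tables.dH[aa] - tables.temperature * tables.dS[aa]
        except KeyError:
            raise UnknownResidue(f"no thermodynamic entry for {aa!r}") from None
    return total


_BASIC = {"Nterm": +1, "H": +1, "K": +1, "R": +1}


def net_charge(seq: str, ph: float, params: PIParams | None = None) -> float:
    """Henderson-Hasselbalch net charge of termini plus ionizable side chains."""
    params = params or PIParams()
    counts = {"Nterm": 1, "Cterm": 1}
    for aa in "CDEHKRY":
        c = seq.count(aa)
        if c:
            counts[aa] = c
    charge = 0.0
    for group, n in counts.items():
        pka = params.pka[group]
        if group in _BASIC:
            charge += n / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(seq: str, params: PIParams | None = None) -> float:
    """pH at which |net charge| <= tolerance.

    Bisection on [0, 14] seeded at ``start_ph``: the pH is raised while the
    net charge is positive and lowered while negative, which is the fixed
    contract of the iterative method; bisection guarantees convergence
    because the net charge is monotone decreasing in pH.
    """
    params = params or PIParams()
    ph = params.start_ph
    lo, hi = 0.0, 14.0
    for _ in range(params.max_iterations):
        q = net_charge(seq, ph, params)
        if abs(q) <= params.tolerance and hi - lo < 1e-6:
            return ph
        if q > 0:
            lo = ph
        else:
            hi = ph
        if hi - lo < 1e-9:
            break
        ph = (lo + hi) / 2.0
    if abs(net_charge(seq, ph, params)) <= params.tolerance:
        return ph
    raise NonConvergence(f"pI not within tolerance after {params.max_iterations} steps")


def mean_pair_pi(vh: str, vl: str, params: PIParams | None = None,
                 concatenated: bool = False) -> float:
    """Mean of the two chain pI values (or pI of the joined string when
    ``concatenated`` — the alternative reading of a pair-level pI)."""
    if concatenated:
        return isoelectric_point(vh + vl, params)
    return (isoelectric_point(vh, params) + isoelectric_point(vl, params)) / 2.0


# ---------------------------------------------------------------------------
# reference statistics and the Z-gate


@dataclass(frozen=True)
class ReferenceStats:
    """Per-feature mean and sample standard deviation of a reference set."""

    mean: dict
    sd: dict
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise InsufficientData(f"need >= 2 records, got {self.n}")


@dataclass(frozen=True)
class StageThresholds:
    """Z threshold per feature; ``None`` switches a feature off (default 2)."""

    z: dict = field(default_factory=lambda: {f: 2.0 for f in PCF_FEATURES})

    def __post_init__(self):
        for feat, z in self.z.items():
            if feat not in PCF_FEATURES:
                raise ValueError(f"unknown PCF feature {feat!r}")
            if z is not None and z < 0:
                raise ValueError(f"Z must be nonnegative for {feat}")

    @classmethod
    def uniform(cls, z: float | None) -> "StageThresholds":
        return cls(z={f: z for f in PCF_FEATURES})


def pcf_features(vh_numbered: NumberedChain, vh_seq: str, vl_seq: str,
                 tables: ThermoTables | None = None,
                 pi_params: PIParams | None = None) -> dict:
    """The five pre-filter features for one paired antibody."""
    return {
        "cdr_h3_length": float(cdr_h3_length(vh_numbered)),
        "dg_vh": delta_g_unfolding(vh_seq, tables),
        "dg_vl": delta_g_unfolding(vl_seq, tables),
        "dg_concat": delta_g_unfolding(vh_seq + vl_seq, tables),
        "mean_pi": mean_pair_pi(vh_seq, vl_seq, pi_params),
    }


def reference_stats(feature_rows: list[dict]) -> ReferenceStats:
    """Mean and sample (n-1) standard deviation per feature."""
    if len(feature_rows) < 2:
        raise InsufficientData(f"need >= 2 records, got {len(feature_rows)}")
    mean, sd = {}, {}
    for feat in PCF_FEATURES:
        vals = np.array([row[feat] for row in feature_rows], dtype=float)
        mean[feat] = float(vals.mean())
        sd[feat] = float(vals.std(ddof=1))
    return ReferenceStats(mean=mean, sd=sd, n=len(feature_rows))


@dataclass(frozen=True)
class FilterDecision:
    retained: bool
    reasons: tuple[str, ...]


def physchem_filter(features: dict, stats_: ReferenceStats,
                    thresholds: StageThresholds,
                    cys_counts: tuple[int, int] | None = None) -> FilterDecision:
    """Retain iff every active feature is within Z sample-sd of the reference
    mean; the cysteine rule (``cys_counts`` = (heavy, light) C counts) is a
    hard rule applied regardless of Z settings."""
    reasons = []
    if cys_counts is not None:
        for chain, count in zip(("heavy", "light"), cys_counts):
            if count > 2:
                reasons.append(f"cysteines:{chain}={count}")
    for feat in PCF_FEATURES:
        z = thresholds.z.get(feat)
        if z is None:
            continue
        dev = abs(features[feat] - stats_.mean[feat])
        if dev > z * stats_.sd[feat]:
            reasons.append(f"{feat}:|{features[feat]:.3g}-{stats_.mean[feat]:.3g}|"
                           f">{z:g}*{stats_.sd[feat]:.3g}")
    return FilterDecision(retained=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# group comparison


def compare_groups(a, b) -> tuple[float, float]:
    """Two-tailed unpaired Mann-Whitney U for group *a* against *b*.

    Exact null enumeration when the combined size is <= 12 and there are no
    ties; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInput("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
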