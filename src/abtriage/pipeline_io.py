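"""End-to-end pipeline orchestration and file I/O.

Stage order is fixed: numbering -> physicochemical filter (PCF) ->
grid padding + encoding -> Layer 1 (kernel-PCA ellipse gate) -> Layer 2
(approved-vs-discontinued classifier).  Encoding happens once per record
and is reused by both layers.  Every stage can be switched off; survivors
of one stage are the only records entering the next.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import layer1 as l1
from . import layer2 as l2
from . import physchem as pc
from .encoding import MockEncoder, get_encoder
from .errors import (
    AbtriageError,
    GridOverflow,
    InsufficientReference,
    IOFailure,
    ParseError,
    UnnumberableSequence,
)
from .numbering import (
    ChainSequence,
    PaddedChainPair,
    load_grid,
    number_chain,
    pad_to_grid,
)

STATUSES = {"approved", "discontinued", "clinical", "library", "query"}
_H_SUFFIXES = ("/H", "_VH")
_L_SUFFIXES = ("/L", "_VL")


@dataclass(frozen=True)
class PairedAntibody:
    """One antibody record: paired chains plus an optional status label."""

    id: str
    heavy: ChainSequence
    light: ChainSequence
    status: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.status is not None and self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


# ---------------------------------------------------------------------------
# readers


def _pair_key(name: str) -> tuple[str, str] | None:
    for suf in _H_SUFFIXES:
        if name.endswith(suf):
            return name[: -len(suf)], "heavy"
    for suf in _L_SUFFIXES:
        if name.endswith(suf):
            return name[: -len(suf)], "light"
    return None


def read_paired_fasta(path) -> tuple[list[PairedAntibody], list[str]]:
    """Pair FASTA records by identifier stem with /H,/L (or _VH,_VL) suffixes.

    Returns (records, problems); unpaired or duplicated ids are skipped and
    reported, not fatal.
    """
    chains: dict[str, dict[str, str]] = {}
    problems: list[str] = []
    try:
        entries = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(str(exc)) from exc
    for rec in entries:
        key = _pair_key(rec.id)
        if key is None:
            problems.append(f"{rec.id}: no /H,/L or _VH,_VL suffix; skipped")
            continue
        stem, side = key
        slot = chains.setdefault(stem, {})
        if side in slot:
            problems.append(f"{stem}: duplicate {side} chain; keeping the first")
            continue
        slot[side] = str(rec.seq).upper()
    records = []
    for stem, slot in chains.items():
        if "heavy" not in slot or "light" not in slot:
            missing = "light" if "heavy" in slot else "heavy"
            problems.append(f"{stem}: missing {missing} chain; skipped")
            continue
        records.append(PairedAntibody(
            id=stem,
            heavy=ChainSequence(id=f"{stem}/H", chain_type="heavy", residues=slot["heavy"]),
            light=ChainSequence(id=f"{stem}/L", chain_type="light", residues=slot["light"]),
        ))
    return records, problems


def read_paired_table(path) -> tuple[list[PairedAntibody], list[str]]:
    """Read a paired CSV/XLSX table with columns id, sequence_heavy,
    sequence_light and optional status."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(path)
        else:
            df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(str(exc)) from exc
    required = {"id", "sequence_heavy", "sequence_light"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"missing columns: {sorted(missing)}")
    records, problems, seen = [], [], set()
    for i, row in df.iterrows():
        rid = str(row["id"])
        if rid in seen:
            problems.append(f"{rid}: duplicate id; skipped")
            continue
        seen.add(rid)
        status = None
        if "status" in df.columns and pd.notna(row.get("status")):
            status = str(row["status"]).strip().lower()
        try:
            records.append(PairedAntibody(
                id=rid,
                heavy=ChainSequence(id=f"{rid}/H", chain_type="heavy",
                                    residues=str(row["sequence_heavy"]).strip().upper()),
                light=ChainSequence(id=f"{rid}/L", chain_type="light",
                                    residues=str(row["sequence_light"]).strip().upper()),
                status=status,
            ))
        except (UnnumberableSequence, ValueError) as exc:
            problems.append(f"{rid}: {exc}; skipped")
    return records, problems


def read_paired(path, fmt: str | None = None) -> tuple[list[PairedAntibody], list[str]]:
    """Dispatch on format: 'fasta' or 'csv' (csv covers xlsx tables too)."""
    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".faa") else "csv"
    if fmt == "fasta":
        return read_paired_fasta(path)
    if fmt == "csv":
        return read_paired_table(path)
    raise ParseError(f"unknown format {fmt!r}")


def extract_bcr_pairs(cells: pd.DataFrame) -> tuple[list[PairedAntibody], dict]:
    """Pair single-cell chains by barcode: one IGH per barcode plus the
    light chain with the highest count when both IG-kappa and IG-lambda are
    present (ties keep the first occurrence).

    ``cells`` columns: barcode, locus (IGH/IGK/IGL), sequence, count.
    Returns (pairs, summary of unpairable barcodes).
    """
    required = {"barcode", "locus", "sequence", "count"}
    missing = required - set(cells.columns)
    if missing:
        raise ParseError(f"missing columns: {sorted(missing)}")
    pairs, no_heavy, no_light = [], 0, 0
    for barcode, grp in cells.groupby("barcode", sort=False):
        heavies = grp[grp["locus"] == "IGH"]
        lights = grp[grp["locus"].isin(("IGK", "IGL"))]
        if heavies.empty:
            no_heavy += 1
            continue
        if lights.empty:
            no_light += 1
            continue
        heavy_row = heavies.iloc[0]
        # stable argmax: first occurrence wins ties
        light_row = lights.iloc[int(np.argmax(lights["count"].to_numpy()))]
        light_type = "kappa" if light_row["locus"] == "IGK" else "lambda"
        pairs.append(PairedAntibody(
            id=str(barcode),
            heavy=ChainSequence(id=f"{barcode}/H", chain_type="heavy",
                                residues=str(heavy_row["sequence"]).upper()),
            light=ChainSequence(id=f"{barcode}/L", chain_type="light",
                                residues=str(light_row["sequence"]).upper()),
            metadata={"light_type": light_type},
        ))
    return pairs, {"paired": len(pairs), "no_heavy": no_heavy, "no_light": no_light}


# ---------------------------------------------------------------------------
# configuration and report types


@dataclass
class PipelineConfig:
    pcf_thresholds: pc.StageThresholds = field(default_factory=pc.StageThresholds)
    pcf_enabled: bool = True
    encoder: str = "mock"
    encoder_dim: int = 8
    layer1_enabled: bool = True
    kpca: l1.KPCAConfig = field(default_factory=l1.KPCAConfig)
    layer1_z: float | str = "all"
    frozen_fit: bool = False
    library_subsample: int = 10_000
    layer2_enabled: bool = True
    layer2_k: int = 2500
    layer2_kind: str = "linear_svc"
    layer2_threshold: float = 0.5
    seed: int = 0

    def seeds(self) -> dict:
        """Named substreams derived from the global seed."""
        ss = np.random.SeedSequence(self.seed)
        enc, sub, cv = ss.spawn(3)
        return {
            "encoder": int(enc.generate_state(1)[0] % (2 ** 31)),
            "subsample": int(sub.generate_state(1)[0] % (2 ** 31)),
            "cv": int(cv.generate_state(1)[0] % (2 ** 31)),
        }


@dataclass
class TriageRow:
    id: str
    numbered: bool = False
    reason: str = ""
    pcf_pass: bool | None = None
    pcf_reasons: str = ""
    layer1_inside: bool | None = None
    pc1: float | None = None
    pc2: float | None = None
    layer2_prob: float | None = None
    layer2_pass: bool | None = None
    final: str = "rejected"


@dataclass
class TriageReport:
    header: dict
    rows: list[TriageRow]

    def survivors(self, stage: str) -> list[str]:
        def alive(r: TriageRow, st: str) -> bool:
            if not r.numbered:
                return False
            if st == "numbering":
                return True
            if r.pcf_pass is False:
                return False
            if st == "pcf":
                return True
            if r.layer1_inside is False:
                return False
            if st == "layer1":
                return True
            return r.layer2_pass is not False
        return [r.id for r in self.rows if alive(r, stage)]


@dataclass(frozen=True)
class ReferenceSets:
    """Reference record lists feeding the three stages."""

    clinical: list = field(default_factory=list)
    library: list = field(default_factory=list)
    approved: list = field(default_factory=list)
    discontinued: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# pipeline


def _number_record(rec: PairedAntibody):
    return number_chain(rec.heavy), number_chain(rec.light)


def _encode_records(records, numbered, encoder, grids):
    """Encode each record once; returns (matrix rows dict, overflow reasons)."""
    vectors, overflow = {}, {}
    gh, gl = grids
    for rec in records:
        nh, nl = numbered[rec.id]
        try:
            pair = PaddedChainPair(
                heavy_padded=pad_to_grid(nh, gh),
                light_padded=pad_to_grid(nl, gl),
                heavy_id=rec.heavy.id, light_id=rec.light.id,
                pad_char=gh.pad_char,
            )
        except GridOverflow as exc:
            overflow[rec.id] = str(exc)
            continue
        vectors[rec.id] = encoder.encode(pair, antibody_id=rec.id).values
    return vectors, overflow


def run_pipeline(query: list[PairedAntibody], refs: ReferenceSets,
                 config: PipelineConfig | None = None,
                 encoder: MockEncoder | None = None) -> TriageReport:
    """Run PCF -> Layer 1 -> Layer 2 over the query records."""
    config = config or PipelineConfig()
    seeds = config.seeds()
    rows = {rec.id: TriageRow(id=rec.id) for rec in query}
    if len(rows) != len(query):
        raise ParseError("duplicate ids in query dataset")

    # numbering (always on: later stages depend on it)
    numbered: dict[str, tuple] = {}
    active: list[PairedAntibody] = []
    for rec in query:
        try:
            numbered[rec.id] = _number_record(rec)
        except UnnumberableSequence as exc:
            rows[rec.id].reason = f"unnumberable:{exc.reason}"
            continue
        rows[rec.id].numbered = True
        active.append(rec)

    header: dict = {
        "config": {
            "encoder": config.encoder, "encoder_dim": config.encoder_dim,
            "pcf_enabled": config.pcf_enabled,
            "pcf_z": {k: v for k, v in config.pcf_thresholds.z.items()},
            "layer1_enabled": config.layer1_enabled,
            "layer1_z": config.layer1_z, "kernel": config.kpca.kernel,
            "gamma": config.kpca.gamma, "frozen_fit": config.frozen_fit,
            "layer2_enabled": config.layer2_enabled, "layer2_k": config.layer2_k,
            "layer2_kind": config.layer2_kind,
            "layer2_threshold": config.layer2_threshold,
            "seed": config.seed,
        },
        "seeds": seeds,
        "dataset_sizes": {
            "query": len(query), "clinical": len(refs.clinical),
            "library": len(refs.library), "approved": len(refs.approved),
            "discontinued": len(refs.discontinued),
        },
    }

    # --- physicochemical filter -------------------------------------------
    if config.pcf_enabled and active:
        stats_source = refs.approved or refs.clinical
        if len(stats_source) < 2:
            raise AbtriageError("PCF stage: need >= 2 approved/clinical reference records")
        ref_rows = []
        for rec in stats_source:
            try:
                nh, nl = _number_record(rec)
            except UnnumberableSequence:
                continue
            ref_rows.append(pc.pcf_features(nh, rec.heavy.residues, rec.light.residues))
        stats = pc.reference_stats(ref_rows)
        header["pcf_reference_n"] = len(ref_rows)
        survivors = []
        for rec in active:
            nh, _ = numbered[rec.id]
            feats = pc.pcf_features(nh, rec.heavy.residues, rec.light.residues)
            cys = (rec.heavy.residues.count("C"), rec.light.residues.count("C"))
            decision = pc.physchem_filter(feats, stats, config.pcf_thresholds,
                                          cys_counts=cys)
            rows[rec.id].pcf_pass = decision.retained
            rows[rec.id].pcf_reasons = ";".join(decision.reasons)
            if decision.retained:
                survivors.append(rec)
        active = survivors

    # --- encoding (once; reused by both layers) ---------------------------
    vectors: dict[str, np.ndarray] = {}
    if (config.layer1_enabled or config.layer2_enabled) and active:
        if encoder is None:
            encoder = get_encoder(config.encoder, dim=config.encoder_dim,
                                  seed=seeds["encoder"])
        grids = (load_grid("heavy", encoder.spec.pad_char),
                 load_grid("light", encoder.spec.pad_char))
        vectors, overflow = _encode_records(active, numbered, encoder, grids)
        for rid, why in overflow.items():
            rows[rid].numbered = False
            rows[rid].reason = f"grid-overflow:{why}"
        active = [rec for rec in active if rec.id in vectors]

        ref_numbered, ref_vectors = {}, {}

        def _ref_encode(records):
            out = {}
            for rec in records:
                if rec.id in ref_vectors:
                    out[rec.id] = ref_vectors[rec.id]
                    continue
                try:
                    ref_numbered[rec.id] = _number_record(rec)
                except UnnumberableSequence:
                    continue
                vecs, _ = _encode_records([rec], ref_numbered, encoder, grids)
                if rec.id in vecs:
                    ref_vectors[rec.id] = vecs[rec.id]
                    out[rec.id] = vecs[rec.id]
            return out

    # --- Layer 1 ----------------------------------------------------------
    if config.layer1_enabled and active:
        clin_vecs = _ref_encode(refs.clinical)
        if len(clin_vecs) < 3:
            raise InsufficientReference(
                "Layer 1: need >= 3 numberable clinical reference records"
            )
        lib_records = list(refs.library)
        if len(lib_records) > config.library_subsample:
            rng = np.random.default_rng(seeds["subsample"])
            keep = rng.choice(len(lib_records), size=config.library_subsample,
                              replace=False)
            lib_records = [lib_records[i] for i in sorted(keep)]
        lib_vecs = _ref_encode(lib_records)
        clin_X = np.array(list(clin_vecs.values()))
        query_X = np.array([vectors[rec.id] for rec in active])
        fit_blocks = [clin_X]
        if lib_vecs:
            fit_blocks.append(np.array(list(lib_vecs.values())))
        if not config.frozen_fit:
            fit_blocks.append(query_X)
        model = l1.fit_kpca(np.vstack(fit_blocks), config.kpca)
        clin_proj = l1.project(model, clin_X)
        query_proj = l1.project(model, query_X)
        ellipse = l1.ellipse_from_reference(clin_proj, config.layer1_z)
        header["layer1"] = {
            "ellipse": {"p1": list(ellipse.p1), "p2": list(ellipse.p2),
                        "h": ellipse.h, "a": ellipse.a, "b": ellipse.b,
                        "theta": ellipse.theta, "center": list(ellipse.center)},
            "fit_rows": int(sum(len(b) for b in fit_blocks)),
        }
        survivors = []
        for rec, (x, y) in zip(active, query_proj):
            inside = l1.point_in_ellipse(ellipse, (x, y))
            r = rows[rec.id]
            r.layer1_inside = bool(inside)
            r.pc1, r.pc2 = float(x), float(y)
            if inside:
                survivors.append(rec)
        active = survivors

    # --- Layer 2 ----------------------------------------------------------
    if config.layer2_enabled and active:
        app_vecs = _ref_encode(refs.approved)
        dis_vecs = _ref_encode(refs.discontinued)
        if not app_vecs or not dis_vecs:
            raise AbtriageError(
                "Layer 2: need numberable approved and discontinued reference records"
            )
        X_train = np.array(list(app_vecs.values()) + list(dis_vecs.values()))
        y_train = np.array([1] * len(app_vecs) + [0] * len(dis_vecs))
        sel = l2.select_k(X_train, y_train, config.layer2_k)
        cols = list(sel.indices)
        model2 = l2.train_classifier(X_train[:, cols], y_train,
                                     kind=config.layer2_kind, seed=seeds["cv"],
                                     threshold=config.layer2_threshold,
                                     selection=sel,
                                     encoder_name=encoder.spec.name)
        query_X = np.array([vectors[rec.id] for rec in active])[:, cols]
        labels, probs = l2.predict(model2, query_X)
        survivors = []
        for rec, lab, prob in zip(active, labels, probs):
            r = rows[rec.id]
            r.layer2_prob = float(prob)
            r.layer2_pass = bool(lab)
            if lab:
                survivors.append(rec)
        active = survivors

    for rec in active:
        rows[rec.id].final = "retained"

    report = TriageReport(header=header, rows=[rows[rec.id] for rec in query])
    report.header["survivors"] = {
        stage: len(report.survivors(stage))
        for stage in ("numbering", "pcf", "layer1", "layer2")
    }
    return report


# ---------------------------------------------------------------------------
# report serialization

_COLUMNS = ("id", "numbered", "reason", "pcf_pass", "pcf_reasons",
            "layer1_inside", "pc1", "pc2", "layer2_prob", "layer2_pass", "final")


def _cell(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)  # shortest exact round-trip form
    return str(value)


def write_report(report: TriageReport, path) -> None:
    """Write the row table as TSV and the run header as a JSON sidecar."""
    path = Path(path)
    try:
        with open(path, "w") as f:
            f.write("\t".join(_COLUMNS) + "\n")
            for row in report.rows:
                d = asdict(row)
                f.write("\t".join(_cell(d[c]) for c in _COLUMNS) + "\n")
        with open(path.with_suffix(path.suffix + ".json"), "w") as f:
            json.dump(report.header, f, indent=1, sort_keys=True)
            f.write("\n")
    except OSError as exc:
        raise IOFailure(str(exc)) from exc


def read_report(path) -> TriageReport:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    rows = []
    with open(path) as f:
        header_line = f.readline().rstrip("\n").split("\t")
        if tuple(header_line) != _COLUMNS:
            raise ParseError("unrecognised report columns", line=1)
        for line in f:
            vals = dict(zip(_COLUMNS, line.rstrip("\n").split("\t")))
            def b(v):
                return None if v == "." else v == "1"
            def fl(v):
                return None if v == "." else float(v)
            rows.append(TriageRow(
                id=vals["id"], numbered=vals["numbered"] == "1",
                reason=vals["reason"], pcf_pass=b(vals["pcf_pass"]),
                pcf_reasons=vals["pcf_reasons"],
                layer1_inside=b(vals["layer1_inside"]),
                pc1=fl(vals["pc1"]), pc2=fl(vals["pc2"]),
                layer2_prob=fl(vals["layer2_prob"]),
                layer2_pass=b(vals["layer2_pass"]), final=vals["final"],
            ))
    with open(path.with_suffix(path.suffix + ".json")) as f:
        header = json.load(f)
    return TriageReport(header=header, rows=rows)
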