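"""Seeded generators with the statistical structure each stage assumes.

Three generators: paired human-like repertoires built from the packaged
template chains (numberable by construction), embedding clouds with a
compact reference cluster inside a radially spread background, and labeled
feature matrices with a known set of informative columns.  All are pure
functions of their spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .numbering import reference_chain, ChainSequence
from .pipeline_io import PairedAntibody

# Positions never mutated: conserved anchors plus every template cysteine
# and tryptophan (keeps records numberable and clear of the cysteine rule).
_SAFE_ALPHABET = "ADEFGHIKLMNPQRSTVY"  # no C (cysteine rule), no W (anchors)


@dataclass(frozen=True)
class RepertoireSpec:
    n: int
    mutation_rate: float = 0.03
    cdr_h3_mean: float = 12.1
    cdr_h3_sd: float = 6.65
    cdr_h3_min: int = 5
    cdr_h3_max: int = 19
    kappa_fraction: float = 0.6
    status: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must lie in [0, 1]")
        if self.cdr_h3_mean <= 0:
            raise ValueError("CDR-H3 mean length must be positive")
        if not 1 <= self.cdr_h3_min <= self.cdr_h3_max:
            raise ValueError("bad CDR-H3 length bounds")


@dataclass(frozen=True)
class EmbeddingCloudSpec:
    n_reference: int
    n_background: int
    dimension: int = 8
    r_ref: float = 1.0
    r_bg: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not self.r_bg > self.r_ref > 0:
            raise ValueError("need r_bg > r_ref > 0")


@dataclass(frozen=True)
class LabeledFeatureSpec:
    n: int
    d: int
    k_informative: int
    effect: float = 2.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.k_informative > self.d:
            raise ValueError("k_informative must be <= d")
        if self.effect < 0:
            raise ValueError("effect size must be nonnegative")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class balance must lie in (0, 1)")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i, aa in enumerate(out):
        if aa in "CW":  # anchors and the cysteine rule stay intact
            continue
        if rng.random() < rate:
            choices = _SAFE_ALPHABET.replace(aa, "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _sample_h3(rng: np.random.Generator, spec: RepertoireSpec) -> str:
    n = int(round(rng.normal(spec.cdr_h3_mean, spec.cdr_h3_sd)))
    n = max(spec.cdr_h3_min, min(spec.cdr_h3_max, n))
    return "".join(_SAFE_ALPHABET[i] for i in rng.integers(len(_SAFE_ALPHABET), size=n))


def generate_repertoire(spec: RepertoireSpec) -> list[PairedAntibody]:
    """Paired template-derived records with resampled CDR-H3 loops and
    point mutations elsewhere; every record is numberable by construction."""
    rng = np.random.default_rng(spec.seed)
    heavy_tpl = reference_chain("heavy_consensus").residues
    kappa_tpl = reference_chain("kappa_consensus").residues
    lambda_tpl = reference_chain("lambda_consensus").residues
    # template CDR-H3 block occupies heavy residues [97, 105)
    h3_start, h3_end = 97, 105
    records = []
    for i in range(spec.n):
        h3 = _sample_h3(rng, spec)
        heavy = (_mutate(rng, heavy_tpl[:h3_start], spec.mutation_rate) + h3
                 + _mutate(rng, heavy_tpl[h3_end:], spec.mutation_rate))
        light_tpl = kappa_tpl if rng.random() < spec.kappa_fraction else lambda_tpl
        light = _mutate(rng, light_tpl, spec.mutation_rate)
        rid = f"syn{i:05d}"
        records.append(PairedAntibody(
            id=rid,
            heavy=ChainSequence(id=f"{rid}/H", chain_type="heavy", residues=heavy),
            light=ChainSequence(id=f"{rid}/L", chain_type="light", residues=light),
            status=spec.status,
        ))
    return records


def generate_embedding_clouds(spec: EmbeddingCloudSpec):
    """(X, labels): reference rows ~ N(0, r_ref^2 I); background rows at
    radii ~ U(r_ref, r_bg) in random directions."""
    rng = np.random.default_rng(spec.seed)
    ref = rng.normal(0.0, spec.r_ref, size=(spec.n_reference, spec.dimension))
    dirs = rng.normal(size=(spec.n_background, spec.dimension))
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    radii = rng.uniform(spec.r_ref, spec.r_bg, size=(spec.n_background, 1))
    bg = dirs / norms * radii
    X = np.vstack([ref, bg])
    labels = np.array(["reference"] * spec.n_reference + ["background"] * spec.n_background)
    return X, labels


def generate_labeled_features(spec: LabeledFeatureSpec):
    """(X, y, informative_indices): informative columns are class-shifted
    unit-variance Gaussians separated by ``effect`` standard deviations."""
    rng = np.random.default_rng(spec.seed)
    n1 = int(round(spec.n * spec.class_balance))
    y = np.array([1] * n1 + [0] * (spec.n - n1))
    rng.shuffle(y)
    X = rng.standard_normal((spec.n, spec.d))
    informative = np.sort(rng.choice(spec.d, size=spec.k_informative, replace=False))
    shift = spec.effect / 2.0
    for j in informative:
        X[:, j] += np.where(y == 1, shift, -shift)
    return X, y, tuple(int(j) for j in informative)
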