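"""Fixed-grid per-residue encoding of padded chain pairs.

A paired encoding is the heavy-chain grid encoding followed by the light
chain, flattened position-major, so index -> (chain, grid slot, channel)
is a fixed bijection.  The deterministic mock encoder draws one frozen
embedding per (grid slot, residue) from a seeded generator, letting the
whole pipeline run and be tested without any language-model weights.
External adapters register only when their packages are importable.
"""

from __future__ import annotations

import importlib.util
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import AdapterUnavailable, PadMismatch
from .numbering import PaddedChainPair, load_grid

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

# Published layout contracts for the external adapters: total paired-encoding
# features and the pad character each model expects.
ADAPTER_CONTRACTS = {
    "antiberty": {"total_features": 130_048, "pad_char": "_", "module": "antiberty"},
    "ablang": {"total_features": 195_072, "pad_char": "*", "module": "ablang"},
    "sapiens": {"total_features": 152_560, "pad_char": "*", "module": "sapiens"},
    "esm": {"total_features": 82_560, "pad_char": "X", "module": "esm"},
}


@dataclass(frozen=True)
class EncoderSpec:
    """Name, per-residue dimension, pad character and declared total size."""

    name: str
    dim: int
    pad_char: str
    total_features: int

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("embedding dimension must be >= 1")


@dataclass(frozen=True)
class LayoutMap:
    """Bijection index -> (chain, grid slot label, embedding channel)."""

    chains: tuple[str, ...]
    slots: tuple[str, ...]
    channels: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.chains)

    def entry(self, index: int) -> tuple[str, str, int]:
        return self.chains[index], self.slots[index], self.channels[index]


@dataclass(frozen=True)
class FeatureVector:
    antibody_id: str
    encoder: str
    values: np.ndarray
    layout: LayoutMap

    def __post_init__(self):
        if len(self.values) != len(self.layout):
            raise ValueError("feature vector length disagrees with layout map")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def build_layout(dim: int) -> LayoutMap:
    """Position-major heavy-then-light layout over the canonical grids."""
    chains, slots, channels = [], [], []
    for chain_type in ("heavy", "light"):
        for label in load_grid(chain_type).positions:
            chains.extend([chain_type] * dim)
            slots.extend([label] * dim)
            channels.extend(range(dim))
    return LayoutMap(chains=tuple(chains), slots=tuple(slots), channels=tuple(channels))


class MockEncoder:
    """Seeded, frozen per-(slot, residue) embedding table; pads encode to 0."""

    def __init__(self, dim: int = 8, seed: int = 0, pad_char: str = "_"):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        n_slots = load_grid("heavy").slot_count + load_grid("light").slot_count
        rng = np.random.default_rng(seed)
        self._table = rng.standard_normal((n_slots, len(AA_ORDER), dim))
        self.spec = EncoderSpec(
            name=f"mock-d{dim}-s{seed}", dim=dim, pad_char=pad_char,
            total_features=n_slots * dim,
        )
        self.calls = 0  # instrumentation: encode invocations

    def encode(self, pair: PaddedChainPair, antibody_id: str = "") -> FeatureVector:
        return encode_pair(pair, self, antibody_id=antibody_id)

    def _slot_embedding(self, slot_index: int, residue: str) -> np.ndarray:
        if residue == self.spec.pad_char:
            return np.zeros(self.spec.dim)
        return self._table[slot_index, _AA_INDEX[residue]]


def encode_pair(pair: PaddedChainPair, encoder: MockEncoder,
                antibody_id: str = "") -> FeatureVector:
    """Encode a padded pair: heavy grid then light grid, position-major."""
    spec = encoder.spec
    if pair.pad_char != spec.pad_char:
        raise PadMismatch(
            f"pair padded with {pair.pad_char!r}, encoder expects {spec.pad_char!r}"
        )
    heavy_n = load_grid("heavy").slot_count
    light_n = load_grid("light").slot_count
    if len(pair.heavy_padded) != heavy_n or len(pair.light_padded) != light_n:
        raise PadMismatch("padded chain lengths disagree with the canonical grids")
    encoder.calls += 1
    rows = [
        encoder._slot_embedding(i, ch)
        for i, ch in enumerate(pair.heavy_padded + pair.light_padded)
    ]
    values = np.concatenate(rows)
    layout = _layout_cache(spec.dim)
    return FeatureVector(antibody_id=antibody_id or pair.heavy_id,
                         encoder=spec.name, values=values, layout=layout)


_layouts: dict[int, LayoutMap] = {}


def _layout_cache(dim: int) -> LayoutMap:
    if dim not in _layouts:
        _layouts[dim] = build_layout(dim)
    return _layouts[dim]


def mock_encoder(dim: int = 8, seed: int = 0, pad_char: str = "_") -> MockEncoder:
    """Construct the deterministic mock encoder; same (seed, dim) -> same table."""
    return MockEncoder(dim=dim, seed=seed, pad_char=pad_char)


def registry() -> dict[str, dict]:
    """Available encoders: the mock always, adapters when importable."""
    available = {"mock": {"pad_char": "_", "kind": "mock"}}
    for name, contract in ADAPTER_CONTRACTS.items():
        if importlib.util.find_spec(contract["module"]) is not None:
            available[name] = {**contract, "kind": "adapter"}
    return available


def get_encoder(name: str, dim: int = 8, seed: int = 0) -> MockEncoder:
    """Resolve an encoder by name; unavailable adapters raise."""
    if name == "mock":
        return mock_encoder(dim=dim, seed=seed)
    if name in ADAPTER_CONTRACTS:
        if name not in registry():
            raise AdapterUnavailable(
                f"encoder {name!r} requires the {ADAPTER_CONTRACTS[name]['module']!r} package"
            )
        raise AdapterUnavailable(f"adapter {name!r} wiring not implemented in this build")
    raise AdapterUnavailable(f"unknown encoder {name!r}")
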