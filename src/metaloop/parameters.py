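"""Parameter specifications and individuals.

An *individual* is one named set of parameter arrays — the unit the outer-loop
optimizers move through parameter space. A :class:`ParameterSpec` declares, per
named parameter, its shape, bounds and kind (continuous or integer), and is the
single source of truth for sampling, clipping and the flat-vector layout the
optimizers operate on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ContractError

__all__ = [
    "ParameterEntry",
    "ParameterSpec",
    "Individual",
    "create_individual",
    "apply_bounds",
]


@dataclass(frozen=True)
class ParameterEntry:
    name: str
    shape: int
    low: float
    high: float
    kind: str = "continuous"  # "continuous" | "integer"

    def __post_init__(self):
        if self.shape < 1:
            raise ConfigurationError(f"parameter {self.name!r}: shape must be >= 1")
        if not self.low < self.high:
            raise ConfigurationError(
                f"parameter {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )
        if self.kind not in ("continuous", "integer"):
            raise ConfigurationError(f"parameter {self.name!r}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class ParameterSpec:
    """Ordered collection of named, bounded parameter arrays."""

    entries: tuple[ParameterEntry, ...]

    def __post_init__(self):
        if len(self.entries) == 0:
            raise ConfigurationError("empty parameter spec")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate parameter names in {names}")

    @classmethod
    def from_dict(cls, entries: dict) -> "ParameterSpec":
        """Build from ``{name: {shape, low, high, kind}}`` (e.g. parsed YAML)."""
        out = []
        for name, e in entries.items():
            out.append(
                ParameterEntry(
                    name=name,
                    shape=int(e.get("shape", 1)),
                    low=float(e["low"]),
                    high=float(e["high"]),
                    kind=e.get("kind", "continuous"),
                )
            )
        return cls(tuple(out))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    @property
    def dimension(self) -> int:
        return sum(e.shape for e in self.entries)

    def flatten(self, values: dict[str, np.ndarray]) -> np.ndarray:
        """Concatenate named arrays into one flat vector (spec order)."""
        return np.concatenate([np.asarray(values[e.name], dtype=float).ravel() for e in self.entries])

    def unflatten(self, vector: np.ndarray) -> dict[str, np.ndarray]:
        vector = np.asarray(vector, dtype=float).ravel()
        if vector.size != self.dimension:
            raise ContractError(
                f"flat vector has {vector.size} entries, spec dimension is {self.dimension}"
            )
        out, offset = {}, 0
        for e in self.entries:
            chunk = vector[offset : offset + e.shape]
            out[e.name] = np.rint(chunk) if e.kind == "integer" else chunk.copy()
            offset += e.shape
        return out

    def lower_vector(self) -> np.ndarray:
        return np.concatenate([np.full(e.shape, e.low) for e in self.entries])

    def upper_vector(self) -> np.ndarray:
        return np.concatenate([np.full(e.shape, e.high) for e in self.entries])


@dataclass
class Individual:
    """One parameter set; ``values`` maps parameter name to array."""

    values: dict[str, np.ndarray]
    id: int = 0
    generation: int = 0

    def flatten(self, spec: ParameterSpec) -> np.ndarray:
        return spec.flatten(self.values)

    def copy(self) -> "Individual":
        return Individual(
            values={k: np.array(v, copy=True) for k, v in self.values.items()},
            id=self.id,
            generation=self.generation,
        )

    def __eq__(self, other):
        if not isinstance(other, Individual):
            return NotImplemented
        return (
            self.id == other.id
            and self.generation == other.generation
            and set(self.values) == set(other.values)
            and all(np.array_equal(self.values[k], other.values[k]) for k in self.values)
        )


def create_individual(
    spec: ParameterSpec, rng: np.random.Generator, *, id: int = 0, generation: int = 0
) -> Individual:
    """Sample a fresh individual uniformly within each parameter's bounds.

    Integer-kind parameters draw uniformly from the integers of
    ``[low, high]`` (both endpoints included). Deterministic given ``rng``.
    """
    values: dict[str, np.ndarray] = {}
    for e in spec.entries:
        if e.kind == "integer":
            lo, hi = int(np.ceil(e.low)), int(np.floor(e.high))
            values[e.name] = rng.integers(lo, hi + 1, size=e.shape).astype(float)
        else:
            values[e.name] = rng.uniform(e.low, e.high, size=e.shape)
    return Individual(values=values, id=id, generation=generation)


def apply_bounds(ind: Individual, spec: ParameterSpec) -> Individual:
    """Clamp every parameter to its declared range (idempotent).

    Integer-kind parameters are rounded to the nearest integer first, then
    clamped. Raises :class:`ContractError` when the individual's parameter
    names do not match the spec.
    """
    if set(ind.values) != set(spec.names):
        raise ContractError(
            f"individual parameters {sorted(ind.values)} do not match spec {sorted(spec.names)}"
        )
    values = {}
    for e in spec.entries:
        v = np.asarray(ind.values[e.name], dtype=float)
        if e.kind == "integer":
            v = np.rint(v)
        values[e.name] = np.clip(v, e.low, e.high)
    return replace_values(ind, values)


def replace_values(ind: Individual, values: dict[str, np.ndarray]) -> Individual:
    return Individual(values=values, id=ind.id, generation=ind.generation)
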