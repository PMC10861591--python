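"""Bundled networks and a seeded random-network generator.

Provides the minimal 4-reactant / 6-reaction toy cycle, a synthetic
17 x 20 aerobic-glycolysis network, and a
pseudo-random sparse integer stoichiometry matrix generator whose outputs
always satisfy the validity constraints (J >= 4, I >= max(6, J+2), no zero
or duplicate reaction columns, every column consuming and producing
something).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .stoich import StoichiometryMatrix, load_matrix

__all__ = [
    "NetworkSpec",
    "NetworkGenerationError",
    "toy_cycle_T1",
    "ag_network",
    "generate_network",
]


class NetworkGenerationError(RuntimeError):
    """Random generation could not satisfy the constraints."""


def toy_cycle_T1() -> StoichiometryMatrix:
    """Minimal valid network: 4 species A-D on a cycle with two chords.

    Columns: A->B, B->C, C->D, D->A, A->C, B->D as signed unit reaction
    vectors; rank 3, nullity 3.  Deterministic and byte-identical across
    calls.
    """
    entries = np.array(
        [
            # r1    r2    r3    r4    r5    r6
            [-1,    0,    0,    1,   -1,    0],  # A
            [ 1,   -1,    0,    0,    0,   -1],  # B
            [ 0,    1,   -1,    0,    1,    0],  # C
            [ 0,    0,    1,   -1,    0,    1],  # D
        ],
        dtype=np.int64,
    )
    return StoichiometryMatrix(
        entries,
        reactant_ids=("A", "B", "C", "D"),
        reaction_ids=("r1", "r2", "r3", "r4", "r5", "r6"),
    )


def ag_network() -> StoichiometryMatrix:
    """Synthetic 17 x 20 aerobic-glycolysis network.

    Glucose to lactate with the hexose monophosphate shunt, TCA cycle,
    oxaloacetate-malate shuttle, Cori cycle, and the pyruvate / citrate /
    mitochondrial-PEP transport reactions.  The lumped integer
    coefficients are this package's own reconstruction of the pathway
    topology and are marked synthetic in the fixture file.
    """
    ref = resources.files("probkd").joinpath("data/ag_synthetic.csv")
    with resources.as_file(ref) as path:
        if not path.exists():  # pragma: no cover - packaging error only
            raise FileNotFoundError(
                "packaged fixture data/ag_synthetic.csv is missing"
            )
        return load_matrix(path, orientation="reactions-as-columns")


@dataclass(frozen=True)
class NetworkSpec:
    """Target shape and sparsity for a random network.

    density is the expected fraction of non-zero entries per reaction
    column (at least 2 non-zeros are always placed); max_coeff bounds the
    magnitude of the integer stoichiometry numbers; mixed_sign forces every
    reaction to consume and produce at least one species.
    """

    J: int
    I_bar: int
    max_coeff: int = 3
    density: float = 0.3
    seed: int = 0
    mixed_sign: bool = True

    def __post_init__(self) -> None:
        if self.J < 4:
            raise ValueError("J >= 4 required for a valid network")
        if self.I_bar < max(6, self.J + 2):
            raise ValueError("I_bar >= max(6, J + 2) required for a valid network")
        if self.max_coeff < 1:
            raise ValueError("max_coeff must be at least 1")
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")


def _random_column(rng: np.random.Generator, spec: NetworkSpec) -> np.ndarray:
    n_nonzero = max(2, int(rng.binomial(spec.J, spec.density)))
    n_nonzero = min(n_nonzero, spec.J)
    col = np.zeros(spec.J, dtype=np.int64)
    pos = rng.choice(spec.J, size=n_nonzero, replace=False)
    mags = rng.integers(1, spec.max_coeff + 1, size=n_nonzero)
    signs = rng.choice([-1, 1], size=n_nonzero)
    if spec.mixed_sign:
        signs[0] = -1
        if n_nonzero > 1:
            signs[1] = 1
    col[pos] = mags * signs
    return col


def generate_network(spec: NetworkSpec, max_attempts: int = 1000) -> StoichiometryMatrix:
    """Seeded pseudo-random integer stoichiometry matrix.

    Columns are redrawn until no duplicates and no zero columns remain;
    identical seeds yield identical matrices.
    """
    rng = np.random.default_rng(spec.seed)
    columns: list[np.ndarray] = []
    seen: set[bytes] = set()
    for _ in range(spec.I_bar):
        for attempt in range(max_attempts):
            col = _random_column(rng, spec)
            key = col.tobytes()
            if col.any() and key not in seen:
                seen.add(key)
                columns.append(col)
                break
        else:
            raise NetworkGenerationError(
                f"could not draw a fresh reaction column in {max_attempts} attempts"
            )
    entries = np.stack(columns, axis=1)
    return StoichiometryMatrix(
        entries,
        reactant_ids=tuple(f"s{j+1}" for j in range(spec.J)),
        reaction_ids=tuple(f"r{i+1}" for i in range(spec.I_bar)),
    )
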