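"""Catalogue of multicentre-trial designs and the nine simulation scenarios.

A :class:`TrialDesign` describes one multicentre randomized trial arm-allocation
design: how many patients each centre recruits and which 1:1 randomization
mechanism assigns them to treatment or control.  The scenario catalogue spans
three mechanisms (exact within-centre balance, trial-wide chance imbalance,
within-centre permuted blocks) crossed with centre compositions ranging from
many small centres to a few large ones, plus a ninth scenario reproducing the
centre composition of a real 46-practice primary-care trial (N = 511,
permuted blocks of 6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import yaml

from .simulate import GenerativeParams

__all__ = [
    "Allocation",
    "TrialDesign",
    "ScenarioSpec",
    "scenario",
    "scenario_ids",
    "validate_design",
    "export_catalogue",
]


class Allocation(str, Enum):
    """1:1 treatment-allocation mechanism."""

    BALANCED = "balanced"  # exact n_j/2 per arm within every centre
    COMPLETE = "complete"  # trial-wide permutation of a fixed 1:1 label vector
    PERMUTED_BLOCK = "permuted_block"  # within-centre permuted blocks


@dataclass(frozen=True)
class TrialDesign:
    """Centre sizes plus the allocation mechanism of one trial design.

    Parameters
    ----------
    centre_sizes
        Number of patients recruited per centre, ``n_j`` for ``j = 1..J``.
    allocation
        One of the :class:`Allocation` mechanisms.
    block_size
        Positive even block length; required iff ``allocation`` is
        ``permuted_block``.
    """

    centre_sizes: tuple[int, ...]
    allocation: Allocation
    block_size: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "centre_sizes", tuple(int(n) for n in self.centre_sizes))
        object.__setattr__(self, "allocation", Allocation(self.allocation))
        violations = validate_design(self)
        if violations:
            raise ValueError("invalid TrialDesign: " + "; ".join(violations))

    @property
    def J(self) -> int:
        """Number of centres."""
        return len(self.centre_sizes)

    @property
    def N(self) -> int:
        """Total number of patients."""
        return sum(self.centre_sizes)


def validate_design(design: TrialDesign | object) -> list[str]:
    """Report violations of the trial-design invariants.

    Returns an empty list iff the design is valid; never raises.  Messages
    identify the violated rule and the offending centre index (1-based).
    """
    msgs: list[str] = []
    sizes = tuple(getattr(design, "centre_sizes", ()))
    if len(sizes) < 1:
        msgs.append("design must contain at least one centre (J >= 1)")
    for j, n in enumerate(sizes, start=1):
        if not isinstance(n, (int,)) or isinstance(n, bool) or n < 1:
            msgs.append(f"centre {j}: size must be a positive integer, got {n!r}")
    try:
        alloc = Allocation(getattr(design, "allocation"))
    except (ValueError, TypeError):
        msgs.append(f"unknown allocation {getattr(design, 'allocation', None)!r}")
        return msgs
    block = getattr(design, "block_size", None)
    if alloc is Allocation.BALANCED:
        for j, n in enumerate(sizes, start=1):
            if isinstance(n, int) and n >= 1 and n % 2 != 0:
                msgs.append(f"centre {j}: odd centre size {n} under balanced allocation")
    if alloc is Allocation.PERMUTED_BLOCK:
        if block is None:
            msgs.append("permuted_block allocation requires a block_size")
        elif block < 2 or block % 2 != 0:
            msgs.append(f"block_size must be a positive even integer, got {block}")
    elif block is not None:
        msgs.append(f"block_size is only meaningful under permuted_block, got {block}")
    return msgs


@dataclass(frozen=True)
class ScenarioSpec:
    """One catalogued simulation scenario: design, ICC grid and true parameters."""

    id: int
    design: TrialDesign
    icc_grid: tuple[float, ...]
    params: GenerativeParams
    description: str = field(default="", compare=False)


#: ICC grid shared by scenarios 1-8.
ICC_GRID = (0.0, 0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.75)

# Operative 17-centre composition for the variable-centre-size scenarios 7-8
# (N = 180; sizes range 1-28, quartiles 5/10/15, mean 10.6, SD 7.8).
VARIABLE_COMPOSITION_180 = (1, 1, 4, 5, 5, 5, 8, 8, 10, 10, 10, 10, 15, 15, 20, 25, 28)

# 46-centre composition of the motivating 511-patient trial:
# {size: number of centres with that size}.
COMPETE2_COMPOSITION = {
    1: 3, 3: 1, 4: 4, 5: 1, 6: 1, 7: 2, 8: 3, 9: 4, 10: 3, 11: 5,
    12: 3, 13: 2, 15: 3, 16: 3, 18: 2, 19: 2, 20: 1, 22: 1, 23: 1, 25: 1,
}


def _compete2_sizes() -> tuple[int, ...]:
    return tuple(size for size, count in sorted(COMPETE2_COMPOSITION.items()) for _ in range(count))


def _default_params() -> GenerativeParams:
    # beta0 = 0 (it cancels in every treatment contrast), medium effect
    # beta1 = 0.5 residual SDs, unit error variance; ICC supplied per cell.
    return GenerativeParams(beta0=0.0, beta1=0.5, sigma_e2=1.0, icc=0.0)


_EQUAL_SIZES = {1: (45, 4), 2: (18, 10), 3: (6, 30)}


def scenario(id: int) -> ScenarioSpec:
    """Return the fully populated catalogue entry for scenario ``id`` (1-9)."""
    if not isinstance(id, int) or isinstance(id, bool) or not 1 <= id <= 9:
        raise ValueError(f"unknown scenario id {id!r}: valid ids are 1..9")

    if id in (1, 2, 3):
        J, n = _EQUAL_SIZES[id]
        design = TrialDesign((n,) * J, Allocation.BALANCED)
        desc = f"balanced design, {J} centres each with {n} subjects"
    elif id in (4, 5, 6):
        J, n = _EQUAL_SIZES[id - 3]
        design = TrialDesign((n,) * J, Allocation.COMPLETE)
        desc = f"chance imbalance, {J} centres each with {n} subjects"
    elif id in (7, 8):
        block = 2 if id == 7 else 4
        design = TrialDesign(VARIABLE_COMPOSITION_180, Allocation.PERMUTED_BLOCK, block_size=block)
        desc = f"unequal centre sizes, 17 centres, permuted blocks of {block}"
    else:  # id == 9
        design = TrialDesign(_compete2_sizes(), Allocation.PERMUTED_BLOCK, block_size=6)
        desc = "46 centres with the COMPETE II composition, permuted blocks of 6"
        params = GenerativeParams.from_variances(beta0=1.34, beta1=1.26, sigma_e2=7.0, sigma_b2=1.0)
        return ScenarioSpec(9, design, (0.125,), params, desc)

    return ScenarioSpec(id, design, ICC_GRID, _default_params(), desc)


def scenario_ids() -> tuple[int, ...]:
    return tuple(range(1, 10))


def export_catalogue(path: str | None = None) -> str:
    """Serialize the nine-scenario catalogue as a human-readable YAML document.

    Returns the YAML text; also writes it to ``path`` when given.
    """
    entries = []
    for sid in scenario_ids():
        spec = scenario(sid)
        entries.append(
            {
                "id": spec.id,
                "description": spec.description,
                "centre_sizes": list(spec.design.centre_sizes),
                "allocation": spec.design.allocation.value,
                "block_size": spec.design.block_size,
                "icc_grid": [float(v) for v in spec.icc_grid],
                "params": {
                    "beta0": spec.params.beta0,
                    "beta1": spec.params.beta1,
                    "sigma_e2": spec.params.sigma_e2,
                    "icc": spec.params.icc,
                    "sigma_b2": spec.params.sigma_b2,
                },
            }
        )
    text = yaml.safe_dump({"scenarios": entries}, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
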