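"""Synthetic patient-level data for multicentre randomized trials.

Outcomes follow the random-intercept linear model

    Y_ij = beta0 + b_0j + beta1 * X_ij + e_ij,

with centre effects ``b_0j ~ N(0, sigma_b^2)`` drawn fresh for every trial and
patient errors ``e_ij ~ N(0, sigma_e^2)``.  The intraclass correlation
``ICC = sigma_b^2 / (sigma_b^2 + sigma_e^2)`` parameterizes the betwen-centre
variance.  Treatment is allocated 1:1 by one of three mechanisms: exact
within-centre balance, a single trial-wide permutation of a fixed 1:1 label
vector (within-centre arm counts then hypergeometric — "chance imbalance"),
or within-centre permuted blocks.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .designs import TrialDesign

__all__ = [
    "GenerativeParams",
    "TrialData",
    "RngStream",
    "icc_to_sigma_b2",
    "allocate",
    "generate_trial",
    "true_se_beta1",
]


def icc_to_sigma_b2(icc: float, sigma_e2: float) -> float:
    """Between-centre variance implied by an ICC at error variance ``sigma_e2``.

    Inverts ``ICC = sigma_b^2 / (sigma_b^2 + sigma_e2)``:

        sigma_b^2 = sigma_e2 * icc / (1 - icc)

    Raises ``ValueError`` outside the domain ``0 <= icc < 1``, ``sigma_e2 > 0``.
    """
    if not 0.0 <= icc < 1.0:
        raise ValueError(f"icc must lie in [0, 1), got {icc}")
    if sigma_e2 <= 0:
        raise ValueError(f"sigma_e2 must be positive, got {sigma_e2}")
    return sigma_e2 * icc / (1.0 - icc)


@dataclass(frozen=True)
class GenerativeParams:
    """True parameters of the random-intercept generative model.

    ``sigma_b2`` is derived from ``icc`` and ``sigma_e2`` and kept consistent:
    the ICC round-trips to machine precision.
    """

    beta0: float
    beta1: float
    sigma_e2: float
    icc: float
    sigma_b2: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma_b2", icc_to_sigma_b2(self.icc, self.sigma_e2))

    @classmethod
    def from_variances(
        cls, beta0: float, beta1: float, sigma_e2: float, sigma_b2: float
    ) -> "GenerativeParams":
        """Construct from explicit variance components instead of the ICC."""
        if sigma_b2 < 0:
            raise ValueError(f"sigma_b2 must be nonnegative, got {sigma_b2}")
        icc = sigma_b2 / (sigma_b2 + sigma_e2)
        obj = cls(beta0, beta1, sigma_e2, icc)
        object.__setattr__(obj, "sigma_b2", float(sigma_b2))
        return obj

    def with_icc(self, icc: float) -> "GenerativeParams":
        return GenerativeParams(self.beta0, self.beta1, self.sigma_e2, icc)


@dataclass(frozen=True)
class RngStream:
    """Reproducible random substream addressed by (seed, path).

    ``path`` is a tuple of nonnegative integers, conventionally
    ``(scenario id, icc key, replicate index)`` with
    ``icc key = round(icc * 1e6)``.  Identical (seed, path) pairs reproduce
    identical draws bit-for-bit.
    """

    seed: int
    path: tuple[int, ...] = ()

    def generator(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=self.path))


def icc_key(icc: float) -> int:
    """Stable integer key identifying an ICC value in an RNG path."""
    return int(round(icc * 1_000_000))


@dataclass
class TrialData:
    """Patient-level records of one (simulated or real) multicentre trial.

    Attributes
    ----------
    centre : int array, 1-based centre id per patient, nondecreasing.
    arm : int array, 0 = control, 1 = treatment.
    y : float array of outcomes.
    design : the TrialDesign the data conform to, or None for user data.
    """

    centre: np.ndarray
    arm: np.ndarray
    y: np.ndarray
    design: "TrialDesign | None" = None

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=np.int64)
        self.arm = np.asarray(self.arm, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.centre) == len(self.arm) == len(self.y)):
            raise ValueError("centre, arm and y must have equal length")
        if self.centre.size == 0:
            raise ValueError("trial data must contain at least one record")
        if not np.all((self.arm == 0) | (self.arm == 1)):
            raise ValueError("arm labels must be 0 (control) or 1 (treatment)")
        if np.any(self.centre < 1):
            raise ValueError("centre ids must be positive integers")

    @property
    def n_patients(self) -> int:
        return int(self.y.size)

    @property
    def n_centres(self) -> int:
        return int(np.unique(self.centre).size)

    def to_csv(self, path_or_buf) -> None:
        """Write records as CSV with header ``centre,arm,y``."""
        import pandas as pd

        pd.DataFrame({"centre": self.centre, "arm": self.arm, "y": self.y}).to_csv(
            path_or_buf, index=False
        )

    @classmethod
    def from_csv(cls, path_or_buf) -> "TrialData":
        """Read records from CSV with columns ``centre,arm,y``."""
        import pandas as pd

        df = pd.read_csv(path_or_buf)
        missing = {"centre", "arm", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"CSV is missing required columns: {sorted(missing)}")
        order = np.argsort(df["centre"].to_numpy(), kind="stable")
        df = df.iloc[order]
        return cls(
            centre=df["centre"].to_numpy(np.int64),
            arm=df["arm"].to_numpy(np.int64),
            y=df["y"].to_numpy(np.float64),
        )


def _permuted_block_labels(n: int, block_size: int, rng: np.random.Generator) -> np.ndarray:
    """Arm labels for one centre of ``n`` patients under permuted blocks.

    Full blocks hold exactly block_size/2 of each arm in uniformly random
    order; an incomplete final block is a uniformly chosen truncation of a
    fresh random permuted block, bounding within-centre imbalance by
    block_size/2.
    """
    half = block_size // 2
    template = np.array([1] * half + [0] * half, dtype=np.int64)
    n_full, rem = divmod(n, block_size)
    blocks = [rng.permutation(template) for _ in range(n_full)]
    if rem:
        blocks.append(rng.permutation(template)[:rem])
    return np.concatenate(blocks) if blocks else np.empty(0, dtype=np.int64)


def allocate(design: "TrialDesign", rng: np.random.Generator) -> np.ndarray:
    """Draw 1:1 treatment labels (one per patient, grouped by centre).

    balanced        exactly n_j/2 per arm within every centre, order permuted.
    complete        one trial-wide uniform permutation of ceil(N/2) treatment
                    and floor(N/2) control labels; within-centre arm counts
                    are then hypergeometric.
    permuted_block  within-centre permuted blocks of the design's block size.
    """
    from .designs import Allocation

    sizes = design.centre_sizes
    if design.allocation is Allocation.BALANCED:
        labels = []
        for n in sizes:
            if n % 2:
                raise ValueError(f"balanced allocation requires even centre sizes, got {n}")
            labels.append(rng.permutation(np.array([1] * (n // 2) + [0] * (n // 2), dtype=np.int64)))
        return np.concatenate(labels)
    if design.allocation is Allocation.COMPLETE:
        N = design.N
        vec = np.array([1] * ((N + 1) // 2) + [0] * (N // 2), dtype=np.int64)
        return rng.permutation(vec)
    # permuted blocks
    return np.concatenate(
        [_permuted_block_labels(n, design.block_size, rng) for n in sizes]
    )


def generate_trial(
    design: "TrialDesign", params: GenerativeParams, rng: np.random.Generator | RngStream
) -> TrialData:
    """Simulate one multicentre trial under the random-intercept model.

    Draw order is fixed (arms, then centre effects, then errors) so a given
    generator state reproduces the trial bit-for-bit.
    """
    if isinstance(rng, RngStream):
        rng = rng.generator()
    sizes = np.asarray(design.centre_sizes, dtype=np.int64)
    centre = np.repeat(np.arange(1, design.J + 1, dtype=np.int64), sizes)
    arm = allocate(design, rng)
    b = rng.normal(0.0, np.sqrt(params.sigma_b2), size=design.J) if params.sigma_b2 > 0 else np.zeros(design.J)
    e = rng.normal(0.0, np.sqrt(params.sigma_e2), size=design.N)
    y = params.beta0 + b[centre - 1] + params.beta1 * arm + e
    return TrialData(centre=centre, arm=arm, y=y, design=design)


def true_se_beta1(
    centre: np.ndarray | Sequence[int],
    arm: np.ndarray | Sequence[int],
    params: GenerativeParams,
) -> float:
    """Standard error of the best linear unbiased (GLS) treatment estimator.

    For a fixed arm assignment, the generalized-least-squares estimator of
    beta1 under V = sigma_e^2 I + sigma_b^2 (block-diagonal within-centre
    ones) has variance [(X' V^-1 X)^-1]_treatment with X = (1, x).  For a
    fully balanced allocation this reduces to sigma_e * sqrt(1/n_t + 1/n_c).
    """
    centre = np.asarray(centre, dtype=np.int64)
    arm = np.asarray(arm, dtype=np.float64)
    se2, sb2 = params.sigma_e2, params.sigma_b2
    # Woodbury: V_j^-1 = (1/se2) (I - c_j J) with c_j = sb2 / (se2 + n_j sb2)
    J = centre.max()
    n_j = np.bincount(centre, minlength=J + 1)[1:].astype(float)
    sx_j = np.bincount(centre, weights=arm, minlength=J + 1)[1:]
    c_j = sb2 / (se2 + n_j * sb2)
    info = np.empty((2, 2))
    info[0, 0] = np.sum(n_j - c_j * n_j**2)
    info[0, 1] = info[1, 0] = np.sum(sx_j - c_j * n_j * sx_j)
    info[1, 1] = np.sum(arm**2) - np.sum(c_j * sx_j**2)
    info /= se2
    det = info[0, 0] * info[1, 1] - info[0, 1] ** 2
    if det <= 0 or not np.isfinite(det):
        raise ValueError("singular GLS information: treatment effect not estimable")
    var_beta1 = info[0, 0] / det
    return float(np.sqrt(var_beta1))
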