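"""Highest-single-agent (HSA) scoring of 7x7 drug combination matrices.

The excess of each combination cell over the better of the two monotherapies
at the same doses is the synergy signal; the summary score is the mean excess
over the interior (both drugs present), with the best contiguous 3x3 interior
window reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import DoseResponseSeries


@dataclass(frozen=True)
class CombinationMatrix:
    """Inhibition surface over a concentration grid including zero doses.

    Row ``i=0`` and column ``j=0`` hold single-agent responses (the other
    drug at dose 0); cell (0, 0) is the untreated well.
    """

    drugA_id: str
    drugB_id: str
    concsA: np.ndarray  # length 7, concsA[0] == 0
    concsB: np.ndarray
    inhibition: np.ndarray  # (7, 7) percent

    def __post_init__(self):
        cA = np.asarray(self.concsA, dtype=float)
        cB = np.asarray(self.concsB, dtype=float)
        inh = np.asarray(self.inhibition, dtype=float)
        if inh.shape != (len(cA), len(cB)):
            raise ValueError("inhibition shape must match concentration grids")
        if cA[0] != 0 or cB[0] != 0:
            raise ValueError("first concentration of each drug must be 0")
        if np.any(np.diff(cA) <= 0) or np.any(np.diff(cB) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.isnan(inh).any():
            coords = np.argwhere(np.isnan(inh)).tolist()
            raise ValueError(f"missing matrix cells at indices {coords}")
        object.__setattr__(self, "concsA", cA)
        object.__setattr__(self, "concsB", cB)
        object.__setattr__(self, "inhibition", inh)

    @classmethod
    def from_long(cls, df: pd.DataFrame, drugA_id: str = "drugA",
                  drugB_id: str = "drugB") -> "CombinationMatrix":
        """Build from a long table with drugA_conc, drugB_conc, inhibition."""
        wide = df.pivot(index="drugA_conc", columns="drugB_conc",
                        values="inhibition").sort_index().sort_index(axis=1)
        if wide.isna().any().any():
            missing = [(float(i), float(j)) for i, j in
                       wide.stack(dropna=False)[lambda s: s.isna()].index]
            raise ValueError(f"missing combination cells at {missing}")
        return cls(drugA_id=drugA_id, drugB_id=drugB_id,
                   concsA=wide.index.to_numpy(),
                   concsB=wide.columns.to_numpy(),
                   inhibition=wide.to_numpy())

    def to_long(self) -> pd.DataFrame:
        rows = [(float(self.concsA[i]), float(self.concsB[j]),
                 float(self.inhibition[i, j]))
                for i in range(len(self.concsA))
                for j in range(len(self.concsB))]
        return pd.DataFrame(rows, columns=["drugA_conc", "drugB_conc",
                                           "inhibition"])


@dataclass(frozen=True)
class SynergyResult:
    drugA_id: str
    drugB_id: str
    excess: np.ndarray  # same shape as the matrix; zero on dose-0 margins
    summary_score: float  # mean excess over interior cells
    max_window_score: float  # best mean over any contiguous 3x3 interior window


def hsa_excess(matrix: CombinationMatrix) -> SynergyResult:
    """HSA excess surface and summary scores.

    excess(i, j) = inhibition(i, j) - max(inhibition(i, 0), inhibition(0, j))
    for i, j >= 1; the dose-0 margins are zero by construction.
    """
    inh = matrix.inhibition
    monoA = inh[:, 0]
    monoB = inh[0, :]
    excess = np.zeros_like(inh)
    excess[1:, 1:] = inh[1:, 1:] - np.maximum(monoA[1:, None], monoB[None, 1:])
    interior = excess[1:, 1:]
    summary = float(interior.mean())
    n_i, n_j = interior.shape
    if n_i < 3 or n_j < 3:
        max_window = summary
    else:
        max_window = max(
            float(interior[i:i + 3, j:j + 3].mean())
            for i in range(n_i - 2) for j in range(n_j - 2))
    return SynergyResult(drugA_id=matrix.drugA_id, drugB_id=matrix.drugB_id,
                         excess=excess, summary_score=summary,
                         max_window_score=max_window)


def dose_response_slices(matrix: CombinationMatrix,
                         fixed_doses_B=None) -> list[DoseResponseSeries]:
    """Dose-response curves of drug A at fixed doses of drug B.

    ``fixed_doses_B=None`` takes every dose of drug B including 0 (the 0
    slice is the drug-A monotherapy row).
    """
    if fixed_doses_B is None:
        fixed_doses_B = matrix.concsB
    series = []
    for dose in fixed_doses_B:
        js = np.nonzero(np.isclose(matrix.concsB, dose))[0]
        if len(js) == 0:
            raise ValueError(
                f"fixed dose {dose!r} not in drug-B concentrations "
                f"{matrix.concsB.tolist()}")
        j = int(js[0])
        series.append(DoseResponseSeries(
            sample_id=f"{matrix.drugA_id}+{matrix.drugB_id}@{dose:g}",
            drug_id=matrix.drugA_id,
            concentrations=matrix.concsA[1:],
            inhibition=matrix.inhibition[1:, j]))
    return series


def score_matrices(matrices) -> pd.DataFrame:
    """Summary table over a collection of combination matrices."""
    rows = []
    for m in matrices:
        r = hsa_excess(m)
        rows.append({"drugA_id": r.drugA_id, "drugB_id": r.drugB_id,
                     "summary_score": r.summary_score,
                     "max_window_score": r.max_window_score})
    return pd.DataFrame(rows)
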