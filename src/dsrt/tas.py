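"""Target addiction scoring: per-target mean drug sensitivity via
polypharmacology, with one-sided permutation significance.

For target ``t`` with inhibitor set of size ``n_t``,

    tas_t = sum(DSS_i for i hitting t) / n_t

Significance permutes the assignment of DSS values to drug ids (membership
fixed), and applies the add-one correction so p is never 0:

    p_t = (1 + #{perm : tas_perm >= tas_obs}) / (n_perm + 1)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TASConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Membership:
    """Potency-thresholded target -> drug sets, plus bookkeeping."""

    drugs_by_target: dict[str, tuple[str, ...]]
    n_dropped_targets: int = 0

    def __len__(self) -> int:
        return len(self.drugs_by_target)


def build_membership(targets_df: pd.DataFrame, potency_cutoff_nM: float = 1000.0,
                     min_drugs_per_target: int = 2,
                     allowed_targets=None) -> Membership:
    """Filter a bioactivity table into target membership sets.

    Records with potency <= cutoff are kept (boundary inclusive); duplicate
    (drug, target) records across endpoints keep the most potent one;
    targets with fewer than ``min_drugs_per_target`` drugs are dropped.
    ``allowed_targets`` optionally restricts scoring (e.g. kinases only).
    """
    if len(targets_df) == 0:
        raise ValueError("empty drug-target map")
    if potency_cutoff_nM <= 0 or min_drugs_per_target < 1:
        raise ValueError("invalid membership parameters")
    df = targets_df.copy()
    if allowed_targets is not None:
        df = df[df["target_id"].isin(set(allowed_targets))]
    # Most potent record wins across duplicate endpoints.
    df = (df.sort_values("potency_nM", kind="mergesort")
          .drop_duplicates(["drug_id", "target_id"], keep="first"))
    df = df[df["potency_nM"] <= potency_cutoff_nM]
    sets = {}
    dropped = 0
    for target_id, grp in df.groupby("target_id", sort=True):
        drugs = tuple(sorted(grp["drug_id"].unique()))
        if len(drugs) < min_drugs_per_target:
            dropped += 1
            continue
        sets[str(target_id)] = drugs
    if dropped:
        logger.info("dropped %d targets below min_drugs_per_target=%d",
                    dropped, min_drugs_per_target)
    return Membership(drugs_by_target=sets, n_dropped_targets=dropped)


def compute_tas(dss: pd.Series, membership: Membership) -> pd.DataFrame:
    """Per-target mean DSS.

    ``dss`` is indexed by drug_id.  Member drugs without a DSS value are
    excluded from that target's mean (n_t adjusted); targets with no scored
    drugs at all are omitted with a log message.
    """
    rows = []
    omitted = 0
    for target_id, drugs in membership.drugs_by_target.items():
        vals = dss.reindex(drugs).dropna()
        if len(vals) == 0:
            omitted += 1
            continue
        rows.append({"target_id": target_id, "tas": float(vals.mean()),
                     "n_t": int(len(vals))})
    if omitted:
        logger.info("omitted %d targets with no scored drugs", omitted)
    return pd.DataFrame(rows, columns=["target_id", "tas", "n_t"])


def permutation_significance(dss: pd.Series, membership: Membership,
                             n_perm: int = 2000,
                             seed: int = 0) -> pd.DataFrame:
    """One-sided permutation p per target (addiction = high score)."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    dss = dss.dropna()
    drug_index = {d: i for i, d in enumerate(dss.index)}
    values = dss.to_numpy(dtype=float)
    perms = rng.permuted(np.tile(values, (n_perm, 1)), axis=1)

    rows = []
    for target_id, drugs in membership.drugs_by_target.items():
        idx = [drug_index[d] for d in drugs if d in drug_index]
        if not idx:
            continue
        obs = values[idx].mean()
        null = perms[:, idx].mean(axis=1)
        p = (1.0 + int(np.sum(null >= obs - 1e-12))) / (n_perm + 1.0)
        rows.append({"target_id": target_id, "p_perm": p})
    return pd.DataFrame(rows, columns=["target_id", "p_perm"])


def tas_profile(dss_df: pd.DataFrame, membership: Membership,
                config: TASConfig, seed: int = 0) -> pd.DataFrame:
    """Full per-sample TAS table: tas, n_t and permutation p per target."""
    config.validate()
    frames = []
    for sample_id, grp in dss_df.groupby("sample_id", sort=True):
        dss = grp.set_index("drug_id")["dss"]
        scores = compute_tas(dss, membership)
        pvals = permutation_significance(dss, membership,
                                         n_perm=config.n_permutations,
                                         seed=seed)
        merged = scores.merge(pvals, on="target_id", how="left")
        merged.insert(0, "sample_id", sample_id)
        frames.append(merged)
    return pd.concat(frames, ignore_index=True)
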