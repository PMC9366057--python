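"""What-if analysis: clamp chosen scales, impute the rest under each network.

The joint of a linear-Gaussian network is multivariate normal, so clamping a
subset of scales yields an exact Gaussian conditional (Schur complement).
The difference table mirrors the study design around clinical scales 2, 7
and 8 (D, Pt, Sc): draw values of one scale from a source network's
marginal, impute the other two under both group networks on the *same*
draws (paired design), and test the paired differences.

Clamping is observational conditioning on the joint, not an intervention;
the default imputation uses conditional means so that identical networks
give exactly zero differences (stochastic draws available via
``impute='draw'``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MmpiBnError
from .gbn import GaussianNetwork, MvnJoint, to_joint_mvn

__all__ = [
    "WhatIfTable",
    "conditional_distribution",
    "clamp_and_sample",
    "whatif_difference_table",
    "whatif_tables_to_frame",
]

DEFAULT_SCALES = ("D", "Pt", "Sc")  # clinical scales 2, 7, 8


@dataclass(frozen=True)
class WhatIfTable:
    """Paired imputation contrast for one clamped scale.

    ``targets`` maps each imputed scale to (mean difference net_a - net_b,
    SD of the paired difference, paired-t p-value); the clamped scale's own
    draws are summarised by ``clamped_mean`` / ``clamped_sd``.
    """

    clamped_scale: str
    n: int
    clamped_mean: float
    clamped_sd: float
    targets: dict[str, tuple[float, float, float]]


def _joint_of(network_or_joint) -> MvnJoint:
    if isinstance(network_or_joint, GaussianNetwork):
        return to_joint_mvn(network_or_joint)
    return network_or_joint


def conditional_distribution(network, clamped: dict[str, float]) -> MvnJoint:
    """Exact Gaussian conditional over the free scales given the clamped ones.

    mean_f|c = mu_f + S_fc S_cc^-1 (x_c - mu_c);
    cov_f|c  = S_ff - S_fc S_cc^-1 S_cf.
    """
    joint = _joint_of(network)
    unknown = set(clamped) - set(joint.nodes)
    if unknown:
        raise ValueError(f"clamped scales not in the network: {sorted(unknown)}")
    free = tuple(n for n in joint.nodes if n not in clamped)
    if not free:
        return MvnJoint((), np.empty(0), np.empty((0, 0)))
    f = [joint.nodes.index(n) for n in free]
    c = [joint.nodes.index(n) for n in joint.nodes if n in clamped]
    if not c:
        return joint
    xc = np.array([clamped[joint.nodes[i]] for i in c], dtype=float)
    s_cc = joint.covariance[np.ix_(c, c)]
    s_fc = joint.covariance[np.ix_(f, c)]
    try:
        w = np.linalg.solve(s_cc, np.column_stack([xc - joint.mean[c],
                                                   joint.covariance[np.ix_(c, f)]]))
    except np.linalg.LinAlgError as exc:
        raise MmpiBnError("clamped block is singular") from exc
    mean = joint.mean[f] + s_fc @ w[:, 0]
    cov = joint.covariance[np.ix_(f, f)] - s_fc @ w[:, 1:]
    return MvnJoint(free, mean, 0.5 * (cov + cov.T))


def clamp_and_sample(network, clamped: dict[str, float], n: int,
                     seed=None) -> pd.DataFrame:
    """``n`` exact draws from the conditional; full profiles are returned
    (clamped columns constant, free columns sampled).  Reproducible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    joint = _joint_of(network)
    cond = conditional_distribution(joint, clamped)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = pd.DataFrame(index=range(n), columns=list(joint.nodes), dtype=float)
    for name, value in clamped.items():
        out[name] = float(value)
    if cond.nodes:
        draws = rng.multivariate_normal(cond.mean, cond.covariance, size=n,
                                        method="svd")
        out.loc[:, list(cond.nodes)] = draws
    return out


def _conditional_mean_coeffs(joint: MvnJoint, clamp: str, target: str
                             ) -> tuple[float, float]:
    """(intercept, slope) of E[target | clamp = x], linear in x."""
    i = joint.nodes.index(target)
    j = joint.nodes.index(clamp)
    var_c = joint.covariance[j, j]
    if var_c <= 0:
        raise MmpiBnError(f"clamped scale {clamp!r} has zero variance")
    slope = joint.covariance[i, j] / var_c
    return float(joint.mean[i] - slope * joint.mean[j]), float(slope)


def _paired_t_p(diff: np.ndarray) -> float:
    sd = diff.std(ddof=1)
    if sd == 0.0:
        return 1.0 if diff.mean() == 0.0 else 0.0
    t = diff.mean() / (sd / np.sqrt(diff.size))
    return float(2 * sps.t.sf(abs(t), diff.size - 1))


def whatif_difference_table(net_a: GaussianNetwork, net_b: GaussianNetwork,
                            source_net: GaussianNetwork | None = None,
                            scales: tuple[str, ...] = DEFAULT_SCALES,
                            n: int = 1000, seed: int = 0,
                            impute: str = "mean") -> list[WhatIfTable]:
    """Paired what-if contrast over ``scales`` between two group networks.

    For each scale s in ``scales``: draw ``n`` values of s from
    ``source_net``'s marginal (default: ``net_b``, the schizophrenia-group
    network), impute every other scale in ``scales`` conditionally under
    ``net_a`` and ``net_b`` on the identical draws, and report the mean
    paired difference (a - b), its SD and a paired-t p-value.

    ``impute='mean'`` uses conditional expectations (identical networks give
    exactly zero differences); ``impute='draw'`` adds conditional noise with
    a shared standard-normal stream across the two networks.
    """
    if impute not in ("mean", "draw"):
        raise ValueError("impute must be 'mean' or 'draw'")
    if net_a.nodes != net_b.nodes:
        raise ValueError("networks must share the node set")
    missing = [s for s in scales if s not in net_a.nodes]
    if missing:
        raise ValueError(f"unknown scales: {missing}")
    source = source_net if source_net is not None else net_b
    joint_a, joint_b = to_joint_mvn(net_a), to_joint_mvn(net_b)
    joint_src = _joint_of(source)
    rng = np.random.default_rng(seed)
    tables: list[WhatIfTable] = []
    for clamp in scales:
        k = joint_src.nodes.index(clamp)
        mu = joint_src.mean[k]
        sd = float(np.sqrt(joint_src.covariance[k, k]))
        draws = rng.normal(mu, sd, size=n)
        targets: dict[str, tuple[float, float, float]] = {}
        for target in scales:
            if target == clamp:
                continue
            vals = {}
            for tag, joint in (("a", joint_a), ("b", joint_b)):
                c0, c1 = _conditional_mean_coeffs(joint, clamp, target)
                vals[tag] = c0 + c1 * draws
            if impute == "draw":
                u = rng.standard_normal(n)  # shared noise stream, paired design
                for tag, joint in (("a", joint_a), ("b", joint_b)):
                    cond = conditional_distribution(joint, {clamp: 0.0})
                    csd = np.sqrt(cond.covariance[cond.nodes.index(target),
                                                  cond.nodes.index(target)])
                    vals[tag] = vals[tag] + csd * u
            diff = vals["a"] - vals["b"]
            targets[target] = (float(diff.mean()),
                               float(diff.std(ddof=1)),
                               _paired_t_p(diff))
        tables.append(WhatIfTable(clamp, n, float(draws.mean()),
                                  float(draws.std(ddof=1)), targets))
    return tables


def whatif_tables_to_frame(tables: list[WhatIfTable]) -> pd.DataFrame:
    """Flatten the tables into one tidy frame (one row per clamp/target pair;
    the clamped scale's own row carries the draw mean/SD)."""
    rows = []
    for t in tables:
        rows.append({"clamped": t.clamped_scale, "target": t.clamped_scale,
                     "mean": t.clamped_mean, "sd": t.clamped_sd,
                     "p_value": np.nan, "n": t.n})
        for target, (mean, sd, p) in t.targets.items():
            rows.append({"clamped": t.clamped_scale, "target": target,
                         "mean": mean, "sd": sd, "p_value": p, "n": t.n})
    return pd.DataFrame(rows)
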