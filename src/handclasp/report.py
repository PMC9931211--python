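"""Publication-style outputs: preference tables, bias coefficients,
consistency arithmetic, and recovery reports.

The preference table mirrors the layout of the study's group-preference
table: one row per style variant (wrist, elbow, forearm, other, palm), the
posterior mean and 95% HPDI of the expected proportion per group, the
group-1 minus group-2 difference, and a strong-evidence flag where the
difference HPDI excludes zero (reported as a boolean column rather than
typography).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import VARIANT_LABELS
from .inference import PosteriorSummary, hpdi, exceedance_prob
from .model import influence


def influence_rank_ratio(beta_rank: float) -> float:
    """Fold change in influence between the top- (rank=1) and bottom-ranked
    (rank=0) individual, all other covariates and the random effect equal."""
    top = influence(0.0, 0, 1.0, 0.0, 0.0, beta_rank)
    bottom = influence(0.0, 0, 0.0, 0.0, 0.0, beta_rank)
    return float(top / bottom)


def derived_contrasts(values: dict) -> dict:
    """Derived differences from a mapping of posterior-mean summary values.

    Consistency mode: feeding the printed posterior means of a published
    summary reproduces its printed difference rows.  Recognized inputs:
    ``sigma_W_young``/``sigma_W_old``, ``m_young``/``m_old``, and per-variant
    group means named ``<variant>_group1`` / ``<variant>_group2``.
    """
    out = {}
    if "sigma_W_young" in values and "sigma_W_old" in values:
        out["sigma_W_young - sigma_W_old"] = values["sigma_W_young"] - values["sigma_W_old"]
    if "m_young" in values and "m_old" in values:
        out["m_young - m_old"] = values["m_young"] - values["m_old"]
    for label in VARIANT_LABELS.values():
        a, b = f"{label}_group1", f"{label}_group2"
        if a in values and b in values:
            out[f"{label}_difference"] = values[a] - values[b]
    return out


def write_summary(summary: PosteriorSummary, out_dir) -> list:
    """Write every summary table as CSV; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in summary.tables().items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False)
        written.append(p)
    return written


def summarize_draws_frame(df: pd.DataFrame, mass: float = 0.95) -> dict:
    """Rebuild the summary tables from an exported draws file.

    ``df`` is the plain columnar format written by the fit command: one row
    per retained draw, one column per scalar parameter plus a chain id.
    Returns the same named tables the fit command writes.
    """
    import re

    from .inference import _mean_hpdi
    from .model import group_mean_transform

    groups = sorted({int(m.group(1)) for c in df.columns
                     for m in [re.fullmatch(r"mu\[(\d+),(\d+)\]", c)] if m})
    if not groups:
        raise ValueError("draws file has no group-mean (mu) columns")
    mu = np.stack([np.column_stack([df[f"mu[{j},{k}]"] for k in range(1, 6)])
                   for j in groups], axis=1)          # (D, J, 5)
    phat = np.stack([group_mean_transform(mu[:, jx]) for jx in range(len(groups))],
                    axis=1)
    rows = []
    for k in range(5):
        row = {"k": k + 1, "variant": VARIANT_LABELS[k + 1]}
        for jx, j in enumerate(groups):
            mn, lo, hi = _mean_hpdi(phat[:, jx, k], mass)
            row[f"group{j}_mean"], row[f"group{j}_lo"], row[f"group{j}_hi"] = mn, lo, hi
        if len(groups) >= 2:
            diff = phat[:, 0, k] - phat[:, 1, k]
            mn, lo, hi = _mean_hpdi(diff, mass)
            row.update(diff_mean=mn, diff_lo=lo, diff_hi=hi,
                       strong_evidence=bool(lo > 0 or hi < 0))
        rows.append(row)
    out = {"preferences": pd.DataFrame(rows)}

    brows = []
    for name in ("beta_a", "beta_age", "beta_sex", "beta_rank"):
        mn, lo, hi = _mean_hpdi(df[name].to_numpy(), mass)
        brows.append({"parameter": name, "mean": mn, "lo": lo, "hi": hi,
                      "exp_mean": float(np.exp(mn)),
                      "strong_evidence": bool(lo > 0 or hi < 0)})
    out["influence"] = pd.DataFrame(brows)

    drows = []
    for name in ("sigma_W", "sigma_W_young", "sigma_W_old", "sigma_I"):
        if name in df.columns:
            mn, lo, hi = _mean_hpdi(df[name].to_numpy(), mass)
            drows.append({"parameter": name, "mean": mn, "lo": lo, "hi": hi})
    if {"sigma_W_young", "sigma_W_old"} <= set(df.columns):
        diff = df["sigma_W_young"].to_numpy() - df["sigma_W_old"].to_numpy()
        mn, lo, hi = _mean_hpdi(diff, mass)
        drows.append({"parameter": "sigma_W_young - sigma_W_old", "mean": mn,
                      "lo": lo, "hi": hi,
                      "p_young_gt_old": exceedance_prob(
                          df["sigma_W_young"], df["sigma_W_old"])})
    out["dispersion"] = pd.DataFrame(drows)

    if {"m_young", "m_old"} <= set(df.columns):
        mrows = []
        for name in ("m_young", "m_old"):
            mn, lo, hi = _mean_hpdi(df[name].to_numpy(), mass)
            mrows.append({"parameter": name, "mean": mn, "lo": lo, "hi": hi})
        diff = df["m_young"].to_numpy() - df["m_old"].to_numpy()
        mn, lo, hi = _mean_hpdi(diff, mass)
        mrows.append({"parameter": "m_young - m_old", "mean": mn, "lo": lo,
                      "hi": hi,
                      "p_young_gt_old": exceedance_prob(df["m_young"], df["m_old"])})
        out["maternal"] = pd.DataFrame(mrows)
    return out


# ---------------------------------------------------------------------------
# Recovery reporting
# ---------------------------------------------------------------------------

def recovery_record(truth: dict, sample, mass: float = 0.95) -> dict:
    """Per-replicate recovery record: estimate, HPDI, and coverage per
    generating parameter shared by the fitted variant."""
    spec = sample.spec
    rec = {}
    beta = sample.flat("beta")
    names = {"beta_a": 0, "beta_age": 1, "beta_sex": 2, "beta_rank": 3}
    for name, idx in names.items():
        lo, hi = hpdi(beta[:, idx], mass)
        rec[name] = {"truth": float(truth[name]), "mean": float(beta[:, idx].mean()),
                     "lo": lo, "hi": hi}
    sig = sample.flat("sigma_W")
    if spec.split_sigma:
        for idx, name in ((0, "sigma_W_young"), (1, "sigma_W_old")):
            lo, hi = hpdi(sig[:, idx], mass)
            rec[name] = {"truth": float(truth[name]),
                         "mean": float(sig[:, idx].mean()), "lo": lo, "hi": hi}
        rec["p_sigma_young_gt_old"] = {
            "truth": float(truth["sigma_W_young"] > truth["sigma_W_old"]),
            "mean": exceedance_prob(sig[:, 0], sig[:, 1]), "lo": np.nan, "hi": np.nan}
    else:
        lo, hi = hpdi(sig[:, 0], mass)
        rec["sigma_W"] = {"truth": float(truth["sigma_W"]),
                          "mean": float(sig[:, 0].mean()), "lo": lo, "hi": hi}
    lo, hi = hpdi(sample.flat("sigma_I"), mass)
    rec["sigma_I"] = {"truth": float(truth["sigma_I"]),
                      "mean": float(sample.flat("sigma_I").mean()), "lo": lo, "hi": hi}
    if spec.maternal:
        mdr = sample.flat("m")
        for idx, name in ((0, "m_young"), (1, "m_old")):
            lo, hi = hpdi(mdr[:, idx], mass)
            rec[name] = {"truth": float(truth[name]),
                         "mean": float(mdr[:, idx].mean()), "lo": lo, "hi": hi}
    for v in rec.values():
        if np.isfinite(v["lo"]):
            v["covered"] = bool(v["lo"] <= v["truth"] <= v["hi"])
    return rec


def recovery_report(records: list) -> pd.DataFrame:
    """Aggregate per-parameter bias, RMSE, and HPDI coverage across replicates."""
    if not records:
        raise ValueError("no recovery records")
    params = [k for k in records[0] if "covered" in records[0][k]]
    rows = []
    for p in params:
        err = np.array([r[p]["mean"] - r[p]["truth"] for r in records])
        cov = np.array([r[p]["covered"] for r in records])
        rows.append({"parameter": p, "n_replicates": len(records),
                     "bias": float(err.mean()),
                     "rmse": float(np.sqrt((err ** 2).mean())),
                     "coverage": float(cov.mean())})
    return pd.DataFrame(rows)


def write_recovery(records: list, report: pd.DataFrame, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "recovery.json").write_text(json.dumps(records, indent=1, default=float))
    report.to_csv(out_dir / "recovery.csv", index=False)
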