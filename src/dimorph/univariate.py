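"""Per-ROI univariate battery and the TIV-dependence correlation table.

Five complementary views of each ROI's female/male contrast are computed
on robust z-scores: (1) a heteroscedastic rank test of a global shift,
(2) the kernel-density overlap index, (3) HD decile differences with
percentile-bootstrap CIs, (4) probability of superiority / Cliff's delta
plus an empirically counted Cohen's U3, and (5) spread and shape
comparisons (IQR ratio, skewness, kurtosis).  Benjamini–Hochberg FDR is
applied across the ROIs within each test family; the nine decile
comparisons inside one ROI are controlled with Hochberg's procedure.

Orientation convention: group A is female throughout, so positive shifts,
deltas, and decile differences mean F > M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .effects import (
    DECILES,
    BootstrapConfig,
    bootstrap_moment_difference,
    classify_magnitude,
    cliff_delta_inference,
    cohens_u3_empirical,
    decile_shift_test,
    derive_rng,
    fdr_adjust,
    global_wmw_test,
    iqr_ratio_test,
    overlap_eta,
)
from .tiv import AnalysisDataset

__all__ = ["UnivariateTable", "run_univariate_battery", "tiv_dependence_correlation"]


@dataclass
class UnivariateTable:
    """Tidy per-family result tables for one analysis dataset.

    Each frame is indexed by ROI.  ``global_test`` carries the HD-median
    shift (F - M) and the rank-test p; ``dominance`` carries PS/delta/U3;
    ``deciles`` has one row per (ROI, decile).  ``direction`` is assigned
    only where the FDR-adjusted global or delta test is significant.
    """

    kind: str
    global_test: pd.DataFrame
    overlap: pd.DataFrame
    deciles: pd.DataFrame
    dominance: pd.DataFrame
    shape: pd.DataFrame
    direction: pd.Series


def run_univariate_battery(ds: AnalysisDataset, cfg: BootstrapConfig) -> UnivariateTable:
    """Run the five-part battery on every ROI of ``ds``.

    Per-ROI bootstrap streams are derived from ``cfg.seed`` and the ROI
    position so results do not depend on which ROIs are analysed together.
    """
    rois = list(ds.roi_labels)
    counts = ds.sex.value_counts()
    if counts.get("F", 0) < 10 or counts.get("M", 0) < 10:
        raise ValueError("run_univariate_battery: need >= 10 subjects per sex")

    glob_rows, over_rows, dom_rows, shape_rows, dec_rows = [], [], [], [], []
    for j, roi in enumerate(rois):
        f = ds.group("F", roi)
        m = ds.group("M", roi)
        try:
            gw = global_wmw_test(f, m, cfg)
            eta = overlap_eta(f, m, cfg, rng=derive_rng(cfg.seed, "overlap", j))
            dec = decile_shift_test(f, m, cfg, rng=derive_rng(cfg.seed, "deciles", j))
            dom = cliff_delta_inference(f, m, cfg)
            u3 = cohens_u3_empirical(f, m, cfg, rng=derive_rng(cfg.seed, "u3", j))
            iqr = iqr_ratio_test(f, m, cfg, rng=derive_rng(cfg.seed, "iqr", j))
            skw = bootstrap_moment_difference(f, m, "skewness", cfg, rng=derive_rng(cfg.seed, "skew", j))
            krt = bootstrap_moment_difference(f, m, "kurtosis", cfg, rng=derive_rng(cfg.seed, "kurt", j))
        except ValueError as err:
            raise ValueError(f"univariate battery failed for ROI {roi!r}: {err}") from err

        glob_rows.append({"roi": roi, "shift": gw["shift"].value, "p": gw["p"]})
        over_rows.append(
            {"roi": roi, "overlap_pct": 100 * eta.value,
             "ci_low": 100 * eta.ci_low, "ci_high": 100 * eta.ci_high}
        )
        dom_rows.append(
            {"roi": roi, "ps_f": dom.ps_a, "ps_m": dom.ps_b, "delta": dom.delta.value,
             "ci_low": dom.delta.ci_low, "ci_high": dom.delta.ci_high, "p": dom.delta.p,
             "label": dom.delta.label, "u3_pct": u3.value, "u3_ci_low": u3.ci_low,
             "u3_ci_high": u3.ci_high}
        )
        shape_rows.append(
            {"roi": roi, "iqr_ratio": iqr.value, "iqr_p": iqr.p,
             "skew_diff": skw.value, "skew_p": skw.p,
             "kurt_diff": krt.value, "kurt_p": krt.p}
        )
        for k in range(9):
            dec_rows.append(
                {"roi": roi, "decile": round(DECILES[k], 1), "hd_f": dec.hd_a[k], "hd_m": dec.hd_b[k],
                 "difference": dec.difference[k], "ci_low": dec.ci_low[k], "ci_high": dec.ci_high[k],
                 "p": dec.p[k], "significant": bool(dec.significant[k]),
                 "label": classify_magnitude(dec.difference[k], "cohen_d")}
            )

    glob = pd.DataFrame(glob_rows).set_index("roi")
    glob["fdr_p"] = fdr_adjust(glob["p"])
    dom = pd.DataFrame(dom_rows).set_index("roi")
    dom["fdr_p"] = fdr_adjust(dom["p"])
    shape = pd.DataFrame(shape_rows).set_index("roi")
    for col in ("iqr_p", "skew_p", "kurt_p"):
        shape[f"fdr_{col}"] = fdr_adjust(shape[col])

    alpha = cfg.alpha
    direction = pd.Series("none", index=glob.index, name="direction")
    flagged = (glob["fdr_p"] < alpha) | (dom["fdr_p"] < alpha)
    direction[flagged & (dom["delta"] > 0)] = "F>M"
    direction[flagged & (dom["delta"] < 0)] = "M>F"

    return UnivariateTable(
        kind=ds.kind,
        global_test=glob,
        overlap=pd.DataFrame(over_rows).set_index("roi"),
        deciles=pd.DataFrame(dec_rows),
        dominance=dom,
        shape=shape,
        direction=direction,
    )


def tiv_dependence_correlation(uni: UnivariateTable, ds: AnalysisDataset) -> pd.DataFrame:
    """Spearman correlations, across the ROIs, between the per-ROI TIV R^2
    and the per-ROI sex-difference estimates: the nine signed decile
    differences, Cliff's delta, Cohen's U3 (centered reading: as reported,
    in percent), and the overlap percent.

    When raw volumes scale heterogeneously with TIV, the ROIs where TIV
    explains more variance also show larger apparent sex differences, so
    these correlations are strongly positive for difference measures (and
    negative for overlap); after a correct adjustment they collapse toward
    zero.  One FDR correction is applied over the 12 rows.
    """
    rois = list(ds.roi_labels)
    r2 = ds.tiv_r2.loc[rois].to_numpy()
    if np.ptp(r2) == 0:
        raise ValueError("tiv_dependence_correlation: TIV R^2 constant across ROIs (rho undefined)")

    rows = []
    dec = uni.deciles
    for q in np.round(DECILES, 1):
        d = dec.loc[dec["decile"] == q].set_index("roi").loc[rois, "difference"].to_numpy()
        rows.append((f"decile_{q:.1f}", d))
    rows.append(("cliff_delta", uni.dominance.loc[rois, "delta"].to_numpy()))
    rows.append(("cohens_u3", uni.dominance.loc[rois, "u3_pct"].to_numpy()))
    rows.append(("overlap", uni.overlap.loc[rois, "overlap_pct"].to_numpy()))

    out = []
    for name, values in rows:
        if np.all(values == values[0]):
            raise ValueError(f"tiv_dependence_correlation: estimate {name!r} constant across ROIs")
        res = stats.spearmanr(r2, values)
        out.append({"statistic": name, "rho": float(res.statistic), "p": float(res.pvalue)})
    table = pd.DataFrame(out).set_index("statistic")
    table["fdr_p"] = fdr_adjust(table["p"])
    return table
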