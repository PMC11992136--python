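"""Gaussian-process normative modeling of EEG features.

A feature's typical developmental trajectory is learned on the control
group only, as a GP regression on standardized covariates (age, sex,
site, data quality) with an anisotropic squared-exponential kernel plus
a white-noise term.  Every subject -- control or carrier -- is then
expressed as a deviation z = (y - mu(x)) / sigma(x), where sigma
includes the learned observation noise so that z is calibrated against
observations (held-out controls should have z ~ N(0, 1)).

Before fitting, extreme feature values are removed with a
percentile-IQR rule: with Q15/Q85 the 15th/85th percentiles and
IQR* = Q85 - Q15, values outside [Q15 - 1.5 IQR*, Q85 + 1.5 IQR*]
are excluded.  Model quality is summarized by the standardized mean
squared error (SMSE = MSE / target variance) under 5-fold
cross-validation on the controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, WhiteKernel, ConstantKernel
from sklearn.model_selection import KFold

COVARIATES = ("age", "sex", "site", "quality_ratio")


@dataclass(frozen=True)
class OutlierRule:
    lower: float = 15.0  # percentile
    upper: float = 85.0
    multiplier: float = 1.5

    def __post_init__(self):
        if not 0 < self.lower < self.upper < 100:
            raise ValueError("need 0 < lower < upper < 100")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")


def filter_outliers(values, rule: OutlierRule = OutlierRule()) -> np.ndarray:
    """Keep mask under the percentile-IQR rule (bounds inclusive).

    Percentiles use linear interpolation between order statistics; with
    zero spread the bounds collapse to the common value and everything
    is kept.
    """
    values = np.asarray(values, float)
    if len(values) < 10:
        raise ValueError("need >= 10 values for outlier filtering")
    q_lo, q_hi = np.percentile(values, [rule.lower, rule.upper])
    iqr = q_hi - q_lo
    lo = q_lo - rule.multiplier * iqr
    hi = q_hi + rule.multiplier * iqr
    return (values >= lo) & (values <= hi)


def smse(predictions, truths) -> float:
    """Mean squared error standardized by the (population) target variance.

    Equals 0 for perfect predictions and exactly 1 for predicting the
    target mean.
    """
    predictions = np.asarray(predictions, float)
    truths = np.asarray(truths, float)
    if len(truths) < 2:
        raise ValueError("need >= 2 test points")
    var = truths.var()
    if var == 0:
        raise ValueError("zero target variance; SMSE undefined")
    return float(np.mean((predictions - truths) ** 2) / var)


def _encode(covariates: pd.DataFrame) -> np.ndarray:
    x = covariates.copy()
    if x["sex"].dtype == object:
        x["sex"] = (x["sex"] == "M").astype(float)  # F=0, M=1
    return x[list(COVARIATES)].to_numpy(dtype=float)


@dataclass
class NormativeFit:
    """Trained normative trajectory for one feature."""

    feature: str
    gp: GaussianProcessRegressor
    x_mean: np.ndarray
    x_scale: np.ndarray
    cov_names: tuple
    smse: float
    n_train: int
    dropped_covariates: tuple = ()
    kernel_: str = ""

    def predict(self, covariates: pd.DataFrame):
        """Predictive mean and SD (noise included) at given covariates."""
        x = _encode(covariates)[:, [COVARIATES.index(c) for c in self.cov_names]]
        xs = (x - self.x_mean) / self.x_scale
        mu, sd = self.gp.predict(xs, return_std=True)
        return mu, np.maximum(sd, 1e-12)


def fit_normative(
    feature_values,
    covariates: pd.DataFrame,
    group_labels,
    feature_name: str = "",
    seed: int = 0,
    n_restarts: int = 3,
    n_folds: int = 5,
    min_train: int = 50,
) -> NormativeFit:
    """Fit the control-group GP normative model for one feature.

    Raises if any non-control row is passed: training on carriers is a
    structural error, not a warning.  Covariates with zero variance are
    dropped (logged on the fit).  SMSE comes from seeded k-fold
    cross-validation over the controls.
    """
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    y = np.asarray(feature_values, float)
    groups = np.asarray(group_labels)
    if np.any(groups != "CTRL"):
        raise ValueError("normative model must be trained on CTRL rows only")
    if len(y) < min_train:
        raise ValueError(f"need >= {min_train} control rows, got {len(y)}")
    x_all = _encode(covariates)
    keep_cols = [i for i in range(x_all.shape[1]) if x_all[:, i].std() > 0]
    dropped = tuple(COVARIATES[i] for i in range(x_all.shape[1]) if i not in keep_cols)
    cov_names = tuple(COVARIATES[i] for i in keep_cols)
    x = x_all[:, keep_cols]
    x_mean, x_scale = x.mean(axis=0), x.std(axis=0)
    xs = (x - x_mean) / x_scale

    def make_gp():
        kernel = ConstantKernel(1.0, (1e-3, 1e4)) * RBF(
            length_scale=np.ones(xs.shape[1]),
            length_scale_bounds=(1e-2, 1e5),
        ) + WhiteKernel(noise_level=0.1, noise_level_bounds=(1e-8, 1e3))
        return GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=n_restarts,
            random_state=seed,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        cv_smse = float("nan")
        if n_folds and n_folds >= 2:
            # cross-validated SMSE on controls
            kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
            preds = np.empty_like(y)
            for train_idx, test_idx in kf.split(xs):
                gp = make_gp()
                gp.fit(xs[train_idx], y[train_idx])
                preds[test_idx] = gp.predict(xs[test_idx])
            cv_smse = smse(preds, y)

        gp = make_gp()
        gp.fit(xs, y)
    return NormativeFit(
        feature=feature_name,
        gp=gp,
        x_mean=x_mean,
        x_scale=x_scale,
        cov_names=cov_names,
        smse=cv_smse,
        n_train=len(y),
        dropped_covariates=dropped,
        kernel_=str(gp.kernel_),
    )


def z_score(fit: NormativeFit, subjects: pd.DataFrame, value_col: str = "value"):
    """Deviation scores z = (y - mu(x)) / sigma(x) for all subjects.

    ``subjects`` needs subject_id, the covariate columns and
    ``value_col``; rows with missing covariates or values are skipped.
    Returns a DataFrame (subject_id, feature, z).
    """
    needed = ["subject_id", value_col, *COVARIATES]
    sub = subjects[needed].dropna()
    mu, sd = fit.predict(sub)
    z = (sub[value_col].to_numpy(dtype=float) - mu) / sd
    return pd.DataFrame(
        {"subject_id": sub["subject_id"].to_numpy(), "feature": fit.feature, "z": z}
    )


def normative_z_table(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    rule: OutlierRule = OutlierRule(),
    seed: int = 0,
    min_train: int = 50,
):
    """Outlier-filter, fit and z-score every feature in a long table.

    ``features`` is long-form (subject_id, feature, value).  The outlier
    rule runs per feature on the pooled sample; the GP trains on the
    surviving controls; z-scores cover all surviving subjects.  Returns
    ``(z_table, reports)`` where reports maps feature -> dict with
    n_excluded, smse, kernel.
    """
    merged = features.merge(cohort, on="subject_id", validate="many_to_one")
    z_frames, reports = [], {}
    for feat, block in merged.groupby("feature", sort=True):
        block = block.dropna(subset=["value", *COVARIATES])
        keep = filter_outliers(block["value"].to_numpy(), rule)
        kept = block[keep]
        ctrl = kept[kept["group"] == "CTRL"]
        fit = fit_normative(
            ctrl["value"].to_numpy(),
            ctrl[list(COVARIATES)],
            ctrl["group"].to_numpy(),
            feature_name=feat,
            seed=seed,
            min_train=min_train,
        )
        z_frames.append(z_score(fit, kept))
        reports[feat] = {
            "n_excluded": int((~keep).sum()),
            "smse": fit.smse,
            "kernel": fit.kernel_,
            "dropped_covariates": list(fit.dropped_covariates),
        }
    return pd.concat(z_frames, ignore_index=True), reports
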