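"""Mixed-effects comparisons across arousal states and summary tables.

The canonical comparison is a Gaussian linear mixed model
``value ~ 1 + state + (1 | subject) + (1 | subject:unit)`` where ``unit`` is
the hemisphere (or arteriole) nested in the subject, estimated by REML.
Each non-reference state is tested against the reference level with a Wald
z-test on its fixed-effect coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

REQUIRED_COLUMNS = ("value", "state", "subject", "unit")


@dataclass
class ComparisonSpec:
    """What to compare: the reference state and random-effect structure."""

    reference: str = "rest"
    unit_intercept: bool = True  # include the subject:unit random intercept


def glme_compare(data: pd.DataFrame, spec: ComparisonSpec | None = None) -> dict:
    """Fit the state-comparison mixed model and test each state vs reference.

    Parameters
    ----------
    data : DataFrame with columns value, state, subject, unit — one row per
        event summary (or per unit-state mean).
    spec : ComparisonSpec

    Returns
    -------
    dict with 'estimates' (DataFrame: coef, se, z, p per term), 'converged',
    'singular' (random-effect variance pinned at zero boundary) and the
    random-effect variance estimates.  A singular subject:unit fit falls back
    to the subject-only random intercept and is flagged.
    """
    spec = spec or ComparisonSpec()
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks required columns: {missing}")
    if data["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects for a mixed model")
    if spec.reference not in set(data["state"]):
        raise ValueError(f"reference level {spec.reference!r} absent from data")
    df = data.copy()
    df["state"] = pd.Categorical(df["state"])
    df["subj_unit"] = df["subject"].astype(str) + ":" + df["unit"].astype(str)
    formula = f"value ~ C(state, Treatment(reference={spec.reference!r}))"

    def _fit(vc):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["subject"],
                                re_formula="1", vc_formula=vc)
            try:
                return model.fit(reml=True, method=["lbfgs", "cg"])
            except Exception:
                return model.fit(reml=True)

    singular = False
    vc = {"unit": "0 + C(subj_unit)"} if spec.unit_intercept else None
    try:
        fit = _fit(vc)
        vcomp = getattr(fit, "vcomp", np.array([]))
        if vc is not None and (not fit.converged or np.any(vcomp < 1e-10)):
            singular = True
    except Exception:
        singular = True
        fit = None
    if vc is not None and (singular or fit is None):
        # boundary (singular) subject:unit variance: subject-only intercept
        fallback = _fit(None)
        if fit is None or not fit.converged:
            fit = fallback
    if fit is None:
        raise RuntimeError("mixed model failed to fit under all fallbacks")
    rows = []
    for name in fit.fe_params.index:
        if name == "Intercept":
            state = spec.reference
        else:
            state = name.split("[T.")[-1].rstrip("]")
        rows.append({
            "term": name,
            "state": state,
            "estimate": float(fit.fe_params[name]),
            "se": float(fit.bse_fe[name]),
            "z": float(fit.fe_params[name] / fit.bse_fe[name]),
            "p": float(fit.pvalues[name]),
        })
    estimates = pd.DataFrame(rows).set_index("state")
    return {
        "estimates": estimates,
        "converged": bool(fit.converged),
        "singular": bool(singular),
        "group_var": float(np.squeeze(fit.cov_re)) if fit.cov_re.size else np.nan,
        "vcomp": np.asarray(getattr(fit, "vcomp", [])),
        "resid_var": float(fit.scale),
        "p_value_type": "wald",
    }


def summarize_states(data: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Per-state mean +/- SD table, averaged within subject first.

    The mean is the across-subject mean of within-subject means; the SD is
    across subjects.  With a single subject the SD is undefined (NaN).
    """
    if "subject" not in data.columns or "state" not in data.columns:
        raise ValueError("data needs 'subject' and 'state' columns")
    per_subject = (
        data.groupby(["state", "subject"], observed=True)[value].mean().reset_index()
    )
    out = per_subject.groupby("state", observed=True)[value].agg(
        mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
        n_subjects="count",
    )
    return out
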