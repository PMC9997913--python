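"""Analysis-phenotype construction on the ETDRS grid.

The pipeline order is fixed: eye-specific covariates (image-quality score,
the five segmentation indicators and refractive error) are regressed out of
each eye's thickness values separately, the two eyes are averaged, and the
averaged values are aggregated over a scope — the whole grid, one of the
three concentric fields (foveal = central subfield, intermediate = inner
ring, peripheral = outer ring), or a single segment.  Residualization keeps
the mean level, so phenotypes remain interpretable in micrometres.

Because the same covariate design is used for every segment of an eye and
both residualization and segment averaging are linear, residualizing per
segment and then aggregating gives exactly the same phenotype as aggregating
first — the fixed order is therefore also the general one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._core import (
    EYE_COVARIATES,
    EYES,
    FIELDS,
    GRID_SCOPE,
    LAYERS,
    SEGMENTS,
    ConfigError,
    SchemaError,
    ThicknessCube,
    ols_fit,
)

#: Valid aggregation scopes: whole grid, three fields, nine single segments.
SCOPES: tuple[str, ...] = (GRID_SCOPE,) + tuple(FIELDS) + SEGMENTS


def compute_refractive_error(spherical, cylindrical):
    """Mean spherical equivalent: spherical + 0.5 x cylindrical (diopters).

    Missing inputs propagate to missing output.
    """
    return spherical + 0.5 * cylindrical


def scope_segments(scope: str) -> tuple[str, ...]:
    if scope == GRID_SCOPE:
        return SEGMENTS
    if scope in FIELDS:
        return FIELDS[scope]
    if scope in SEGMENTS:
        return (scope,)
    raise ConfigError(f"unknown scope {scope!r}; expected one of {SCOPES}")


def eye_covariate_table(covariates: pd.DataFrame, eye: str) -> pd.DataFrame:
    """Eye-specific covariate design: quality, 5 indicators, refraction."""
    cols = {}
    for name in EYE_COVARIATES:
        col = f"{name}_{eye}"
        if col not in covariates.columns:
            raise SchemaError(f"covariate table missing column {col!r}")
        cols[name] = covariates[col]
    out = pd.DataFrame(cols, index=covariates.index)
    out["refraction"] = compute_refractive_error(out.pop("spherical"),
                                                 out.pop("cylindrical"))
    return out


def residualize_eye(values, covariates: pd.DataFrame):
    """OLS residuals of thickness on eye covariates, mean level preserved.

    ``values`` is a Series or (n, m) array aligned to ``covariates``; rows
    with any missing covariate or thickness value are passed through as NaN.
    Collinear covariate columns are dropped with a warning.  The returned
    residuals are orthogonal to every covariate and have the same mean as
    the input (the fitted mean is added back as an offset).
    """
    arr = np.asarray(values, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    X = np.column_stack([np.ones(len(covariates)),
                         covariates.to_numpy(dtype=float)])
    ok = np.isfinite(X).all(axis=1) & np.isfinite(arr).all(axis=1)
    out = np.full_like(arr, np.nan)
    if ok.sum() > X.shape[1]:
        names = ["intercept"] + list(covariates.columns)
        for j in range(arr.shape[1]):
            fit = ols_fit(arr[ok, j], X[ok], names=names)
            fitted = X[ok][:, ~np.isnan(fit.beta)] @ fit.beta[
                ~np.isnan(fit.beta)]
            out[ok, j] = arr[ok, j] - fitted + arr[ok, j].mean()
    elif ok.any():
        out[ok] = arr[ok]  # too few rows to fit: pass through
    result = out[:, 0] if squeeze else out
    if isinstance(values, pd.Series):
        return pd.Series(result, index=values.index, name=values.name)
    return result


def average_eyes(left, right):
    """Mean of the available eyes; missing only if both eyes are missing.

    Returns ``(mean, single_eye_flag)``; single-eye individuals are retained
    using the available eye and flagged.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    stacked = np.stack([left, right])
    present = ~np.isnan(stacked)
    count = present.sum(axis=0)
    total = np.where(present, stacked, 0.0).sum(axis=0)
    mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    single = np.isnan(left) ^ np.isnan(right)
    return mean, single


def aggregate_field_mean(cube: ThicknessCube, layer: str, scope: str,
                         covariates: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Residualize per eye, average eyes, then mean over the scope segments.

    With ``covariates=None`` the residualization step is skipped (useful for
    raw-thickness summaries).  Returns a tidy frame with columns
    individual_id, layer, scope, value_um, single_eye.
    """
    if layer not in LAYERS:
        raise ConfigError(f"unknown layer {layer!r}")
    segs = scope_segments(scope)
    seg_idx = [SEGMENTS.index(s) for s in segs]
    per_eye = []
    for eye in EYES:
        vals = cube.layer_eye(layer, eye)[:, seg_idx]
        if covariates is not None:
            design = eye_covariate_table(covariates.loc[cube.individuals],
                                         eye)
            vals = residualize_eye(vals, design)
        per_eye.append(vals.mean(axis=1))  # mean over scope segments
    value, single = average_eyes(per_eye[0], per_eye[1])
    return pd.DataFrame({
        "individual_id": cube.individuals,
        "layer": layer,
        "scope": scope,
        "value_um": value,
        "single_eye": single,
    })


def build_phenotypes(cube: ThicknessCube, covariates: pd.DataFrame,
                     layers=LAYERS, scopes=SCOPES) -> pd.DataFrame:
    """All (layer, scope) phenotype vectors as one tidy table."""
    frames = [aggregate_field_mean(cube, layer, scope, covariates)
              for layer in layers for scope in scopes]
    return pd.concat(frames, ignore_index=True)


def phenotype_series(table: pd.DataFrame, layer: str, scope: str) -> pd.Series:
    """Extract one (layer, scope) phenotype as a Series indexed by id."""
    sel = table[(table["layer"] == layer) & (table["scope"] == scope)]
    if sel.empty:
        raise ConfigError(f"no phenotype rows for ({layer!r}, {scope!r})")
    return pd.Series(sel["value_um"].to_numpy(),
                     index=pd.Index(sel["individual_id"],
                                    name="individual_id"),
                     name=f"{layer}_{scope}")
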