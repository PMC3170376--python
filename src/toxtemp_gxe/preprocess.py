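"""Within- and between-array normalization plus recursive outlier removal.

The raw two-channel intensities are decomposed into per-spot log-ratios
(M) and mean log-intensities (A).  Within each array a locally weighted
polynomial regression of M on A is subtracted; between arrays the A
distributions are equalized by quantile normalization.  Channel-level
log2 intensities are then rebuilt (A +/- M/2) so that reference channels
supply toxicant-free observations for the factorial model downstream.

Outliers are removed per gene by recursively deleting the single most
extreme externally-studentized residual that falls outside a two-sided
confidence interval of the reference t distribution, refitting after
every deletion, with a hard cap on the number of removals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MAPair",
    "ExpressionMatrix",
    "OutlierConfig",
    "ma_transform",
    "loess_fit",
    "loess_normalize_within_array",
    "aquantile_between_arrays",
    "channels_from_ma",
    "remove_outliers_recursive",
    "remove_outliers_matrix",
    "load_geo_series_matrix",
]


@dataclass
class MAPair:
    """Per-spot log-ratio / mean-intensity decomposition of one array.

    ``mask`` is True where a spot is invalid (a non-positive or missing
    channel); masked spots carry NaN in M and A and are ignored by every
    downstream fit.
    """

    gene_ids: np.ndarray
    M: np.ndarray
    A: np.ndarray
    mask: np.ndarray
    array_id: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids)
        self.M = np.asarray(self.M, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.gene_ids) == len(self.M) == len(self.A) == len(self.mask)):
            raise ValueError("gene_ids, M, A and mask must have equal length")

    def copy(self) -> "MAPair":
        return MAPair(
            self.gene_ids.copy(), self.M.copy(), self.A.copy(), self.mask.copy(), self.array_id
        )


@dataclass
class ExpressionMatrix:
    """Normalized log2 intensities, genes x observations, with a mask.

    ``values`` and ``mask`` share index (gene_id) and columns
    (observation_id); mask True means missing or removed.  ``sample_sheet``
    has one row per observation (index = observation_id).
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise ValueError("values and mask must be aligned")
        missing = self.values.columns.difference(self.sample_sheet.index)
        if len(missing):
            raise ValueError(f"sample sheet missing observations: {list(missing)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class OutlierConfig:
    ci_level: float = 0.995
    max_remove: int = 6

    def __post_init__(self) -> None:
        if not (0.5 < self.ci_level < 1.0):
            raise ValueError(f"ci_level must be in (0.5, 1), got {self.ci_level}")
        if self.max_remove < 0:
            raise ValueError(f"max_remove must be >= 0, got {self.max_remove}")


def ma_transform(
    red: np.ndarray, green: np.ndarray, gene_ids=None, array_id: str = ""
) -> MAPair:
    """M = log2(red) - log2(green), A = mean log2 intensity.

    Spots where either channel is non-positive or non-finite are masked
    rather than raising.
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if red.shape != green.shape:
        raise ValueError("red and green must have the same shape")
    if gene_ids is None:
        gene_ids = np.arange(red.size)
    mask = ~(np.isfinite(red) & np.isfinite(green) & (red > 0) & (green > 0))
    lr = np.full(red.shape, np.nan)
    lg = np.full(red.shape, np.nan)
    ok = ~mask
    lr[ok] = np.log2(red[ok])
    lg[ok] = np.log2(green[ok])
    return MAPair(gene_ids, lr - lg, 0.5 * (lr + lg), mask, array_id)


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.3,
    degree: int = 2,
    iterations: int = 3,
    _chunk: int = 512,
) -> np.ndarray:
    """Locally weighted polynomial regression fit evaluated at each x.

    Nearest-neighbour windows covering ``span`` of the data, tricube
    weights, and ``iterations`` bisquare robustifying passes.  A local
    polynomial of the given degree is solved per point; the default
    degree 2 reproduces a noise-free global quadratic exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not (0.0 < span <= 1.0):
        raise ValueError(f"span must be in (0, 1], got {span}")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    k = int(np.ceil(span * n))
    k = min(n, max(k, degree + 2))
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]

    left = np.empty(n, dtype=np.intp)
    lo = 0
    for i in range(n):
        while lo + k < n and xs[lo + k] - xs[i] < xs[i] - xs[lo]:
            lo += 1
        left[i] = lo
    offsets = np.arange(k)

    robust = np.ones(n)
    fitted = np.empty(n)
    p1 = degree + 1
    pq = np.add.outer(np.arange(p1), np.arange(p1))
    for it in range(iterations + 1):
        for start in range(0, n, _chunk):
            stop = min(start + _chunk, n)
            idx = left[start:stop, None] + offsets[None, :]
            xw = xs[idx] - xs[start:stop, None]
            dist = np.abs(xw)
            h = dist.max(axis=1, keepdims=True)
            h[h == 0] = 1.0
            w = np.clip(1.0 - (dist / h) ** 3, 0.0, None) ** 3
            w *= robust[idx]
            # weighted moments S_m = sum w x^m, T_m = sum w x^m y
            wy = w * ys[idx]
            S = np.empty((stop - start, 2 * degree + 1))
            T = np.empty((stop - start, p1))
            S[:, 0] = w.sum(axis=1)
            T[:, 0] = wy.sum(axis=1)
            cur = xw
            for m in range(1, 2 * degree + 1):
                S[:, m] = (w * cur).sum(axis=1)
                if m <= degree:
                    T[:, m] = (wy * cur).sum(axis=1)
                if m < 2 * degree:
                    cur = cur * xw
            normal = S[:, pq]
            normal = normal + np.eye(p1) * 1e-12  # guard against tied-x singularity
            beta = np.linalg.solve(normal, T[..., None])[..., 0]
            fitted[start:stop] = beta[:, 0]
        if it < iterations:
            resid = ys - fitted
            scale = np.median(np.abs(resid))
            if scale <= 1e-9 * max(1.0, float(np.abs(ys).max())):
                break  # numerically perfect fit; robustifying would misfire
            u = resid / (6.0 * scale)
            robust = np.clip(1.0 - u**2, 0.0, None) ** 2
    out = np.empty(n)
    out[order] = fitted
    return out


def loess_normalize_within_array(
    ma: MAPair, span: float = 0.3, degree: int = 2, iterations: int = 3
) -> MAPair:
    """Subtract the loess trend of M on A; A and masked spots untouched."""
    ok = ~ma.mask
    n_ok = int(ok.sum())
    required = max(10, degree + 2)
    if n_ok < required:
        raise ValueError(
            f"array {ma.array_id!r}: {n_ok} unmasked spots, need >= {required} for loess"
        )
    out = ma.copy()
    trend = loess_fit(ma.A[ok], ma.M[ok], span=span, degree=degree, iterations=iterations)
    out.M[ok] = ma.M[ok] - trend
    return out


def aquantile_between_arrays(ma_list: list[MAPair]) -> list[MAPair]:
    """Equalize the A-value distributions across arrays; M untouched.

    Each array's A quantile function is replaced by the across-array mean
    quantile function; tied A values share the average of their target
    quantiles.  Arrays must carry identical spot (gene) sets.
    """
    if len(ma_list) < 2:
        raise ValueError("need at least 2 arrays for between-array normalization")
    ref = list(ma_list[0].gene_ids)
    for ma in ma_list[1:]:
        if list(ma.gene_ids) != ref:
            extra = set(map(str, ma.gene_ids)) - set(map(str, ref))
            missing = set(map(str, ref)) - set(map(str, ma.gene_ids))
            raise ValueError(
                f"array {ma.array_id!r} spot set differs from {ma_list[0].array_id!r}: "
                f"extra={sorted(extra)[:10]}, missing={sorted(missing)[:10]}"
            )
    n = len(ref)
    probs = np.linspace(0.0, 1.0, n)
    quantiles = []
    for ma in ma_list:
        valid = ma.A[~ma.mask]
        if valid.size == 0:
            raise ValueError(f"array {ma.array_id!r} has no unmasked spots")
        quantiles.append(np.quantile(valid, probs))
    target = np.mean(quantiles, axis=0)

    out = []
    for ma in ma_list:
        new = ma.copy()
        ok = ~ma.mask
        valid = ma.A[ok]
        m = valid.size
        if m == 1:
            new.A[ok] = target.mean()
        else:
            ranks = stats.rankdata(valid, method="average")
            new.A[ok] = np.interp((ranks - 1.0) / (m - 1.0), probs, target)
        out.append(new)
    return out


def channels_from_ma(ma_list: list[MAPair], sample_sheet: pd.DataFrame) -> ExpressionMatrix:
    """Rebuild per-channel log2 intensities A +/- M/2 as an observation matrix.

    Observation ids follow ``<array_id>.<channel>`` and must each appear in
    the sample sheet, which labels control channels with cpf = dzn = 0.
    """
    if not ma_list:
        raise ValueError("empty MA list")
    gene_index = pd.Index(ma_list[0].gene_ids, name="gene_id")
    values: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for ma in ma_list:
        for channel, sign in (("red", 0.5), ("green", -0.5)):
            obs = f"{ma.array_id}.{channel}"
            if obs not in sample_sheet.index:
                raise ValueError(f"sample sheet missing observation {obs!r}")
            values[obs] = ma.A + sign * ma.M
            masks[obs] = ma.mask.copy()
    order = [o for o in sample_sheet.index if o in values]
    if len(order) != len(values):
        raise ValueError("sample sheet does not cover all arrays")
    vdf = pd.DataFrame({o: values[o] for o in order}, index=gene_index)
    mdf = pd.DataFrame({o: masks[o] for o in order}, index=gene_index)
    return ExpressionMatrix(vdf, mdf, sample_sheet.loc[order])


def _studentized_residuals(y: np.ndarray, X: np.ndarray):
    """Externally studentized residuals of an OLS fit.

    Returns ``(t_resid, df_resid)`` where df_resid is the residual df of
    the fit itself (the studentized reference distribution has one fewer).
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    q, _ = np.linalg.qr(X)
    hat = np.sum(q**2, axis=1)
    sse = float(resid @ resid)
    df_resid = n - p
    denom = np.clip(1.0 - hat, 1e-12, None)
    s2_loo = (sse - resid**2 / denom) / max(df_resid - 1, 1)
    s2_loo = np.clip(s2_loo, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = resid / np.sqrt(s2_loo * denom)
    t[~np.isfinite(t)] = np.where(np.abs(resid[~np.isfinite(t)]) > 0, np.inf, 0.0)
    return t, df_resid


def remove_outliers_recursive(
    values: np.ndarray,
    design: np.ndarray,
    config: OutlierConfig | None = None,
    mask: np.ndarray | None = None,
):
    """Recursively delete confidence-interval-violating observations.

    At each step the gene's linear model is refit on the active
    observations; if any externally studentized residual falls outside the
    two-sided ``ci_level`` interval of the t distribution, the single most
    extreme observation is removed.  Stops when none exceed the bound,
    when ``max_remove`` deletions have been made, or when a further
    deletion would leave fewer than 2 residual degrees of freedom.

    Returns ``(mask, removals)`` where removals is a list of
    ``(observation_index, iteration, studentized_residual)`` records.
    An all-masked gene is returned unchanged with an empty removal list.
    """
    config = config or OutlierConfig()
    y = np.asarray(values, dtype=float)
    X = np.asarray(design, dtype=float)
    mask = np.zeros(y.size, dtype=bool) if mask is None else np.asarray(mask, dtype=bool).copy()
    mask |= ~np.isfinite(y)
    removals: list[tuple[int, int, float]] = []
    if mask.all():
        return mask, removals
    p = np.linalg.matrix_rank(X)
    upper = 0.5 + config.ci_level / 2.0
    for iteration in range(1, config.max_remove + 1):
        active = np.nonzero(~mask)[0]
        df_resid = active.size - p
        if df_resid - 1 < 2:  # a removal would drop residual df below 2
            break
        t_resid, _ = _studentized_residuals(y[active], X[active])
        crit = stats.t.ppf(upper, df_resid - 1)
        extreme = np.abs(t_resid)
        worst = int(np.argmax(extreme))
        if not (extreme[worst] > crit):
            break
        obs = int(active[worst])
        mask[obs] = True
        removals.append((obs, iteration, float(t_resid[worst])))
    return mask, removals


def remove_outliers_matrix(
    matrix: ExpressionMatrix, design: np.ndarray, config: OutlierConfig | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Apply recursive outlier removal to every gene of a matrix.

    Returns a matrix with an updated mask and a removal log with one row
    per deleted observation.
    """
    config = config or OutlierConfig()
    new_mask = matrix.mask.to_numpy().copy()
    log_rows = []
    values = matrix.values.to_numpy()
    obs_ids = matrix.values.columns
    for g, gene_id in enumerate(matrix.values.index):
        mask_g, removals = remove_outliers_recursive(
            values[g], design, config, mask=new_mask[g]
        )
        new_mask[g] = mask_g
        for obs, iteration, t_val in removals:
            log_rows.append(
                {
                    "gene_id": gene_id,
                    "observation_id": obs_ids[obs],
                    "iteration": iteration,
                    "studentized_residual": t_val,
                }
            )
    out = ExpressionMatrix(
        matrix.values.copy(),
        pd.DataFrame(new_mask, index=matrix.mask.index, columns=matrix.mask.columns),
        matrix.sample_sheet,
    )
    log = pd.DataFrame(
        log_rows, columns=["gene_id", "observation_id", "iteration", "studentized_residual"]
    )
    return out, log


def load_geo_series_matrix(path) -> pd.DataFrame:
    """Minimal loader for GEO series-matrix text files (optional stub).

    Parses the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` into a DataFrame indexed by probe id.
    """
    rows = []
    header = None
    inside = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if not inside or not line:
                continue
            fields = [f.strip('"') for f in line.split("\t")]
            if header is None:
                header = fields
            else:
                rows.append(fields)
    if header is None:
        raise ValueError(f"{path}: no series-matrix table found")
    df = pd.DataFrame(rows, columns=header).set_index(header[0])
    return df.apply(pd.to_numeric, errors="coerce")
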