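"""De-novo mutational-signature extraction and per-sample refitting.

The model is the standard non-negative factorization of a samples x 96
spectrum V into exposures E (samples x k) and signature profiles P (k x 96),
V ~ E P, fit under the generalized Kullback-Leibler divergence with
multiplicative updates and random restarts. Rank is chosen by the trade-off
between bootstrap signature stability (silhouette over cosine distance of
pooled resampled profiles) and reconstruction error.

Per-sample refitting against a fixed reference catalogue uses forward
selection with non-negative least squares re-optimization, a maximum number
of signatures (default 3) and a minimum retained weight (default 0.15):
weights below the cutoff are zeroed and the rest renormalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import NMF
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .spectrum import COSMIC_CHANNELS, NATIVE_CHANNELS, to_native_convention


@dataclass
class SignatureExtraction:
    """A fitted factorization with its diagnostics."""

    k: int
    profiles: pd.DataFrame  # k x 96, rows sum to 1
    exposures: pd.DataFrame  # samples x k, non-negative
    reconstruction_error: float  # KL divergence of the best restart
    seed: int
    n_restarts: int
    stability: pd.Series | None = None  # per-signature silhouette, if computed
    n_resamples: int = 0


def _check_spectrum(spectrum: pd.DataFrame) -> np.ndarray:
    V = spectrum.to_numpy(dtype=float)
    if (V < 0).any():
        raise ValueError("spectrum contains negative counts")
    zero_rows = spectrum.index[V.sum(axis=1) == 0].tolist()
    if zero_rows:
        raise ValueError(
            f"all-zero sample rows {zero_rows}: exclude zero-mutation samples before NMF"
        )
    return V


def nmf_factorize(
    spectrum: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 5000,
    tol: float = 1e-6,
) -> SignatureExtraction:
    """Fit a rank-``k`` KL-NMF, keeping the lowest-divergence restart.

    Profiles (rows of H) are normalized to sum 1 with the scale absorbed into
    the exposures, so exposures are in mutation-count units. Deterministic
    given ``(seed, n_restarts)``.
    """
    if k < 1:
        raise ValueError("rank must be >= 1")
    if k >= len(spectrum) and len(spectrum) > 1:
        raise ValueError("rank must be smaller than the number of samples")
    V = _check_spectrum(spectrum)
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        restart_seed = int(rng.integers(0, 2**31 - 1))
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="kullback-leibler",
            max_iter=max_iter,
            tol=tol,
            random_state=restart_seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = model.fit_transform(V)
        err = float(model.reconstruction_err_)
        if best is None or err < best[0]:
            best = (err, W, model.components_)
    err, W, H = best
    scale = H.sum(axis=1)
    H = H / scale[:, None]
    W = W * scale[None, :]
    names = [f"sig{i + 1}" for i in range(k)]
    profiles = pd.DataFrame(H, index=names, columns=spectrum.columns)
    exposures = pd.DataFrame(W, index=spectrum.index, columns=names)
    return SignatureExtraction(k, profiles, exposures, err, seed, n_restarts)


def _pooled_resample_profiles(
    V: np.ndarray, k: int, n_resamples: int, rng: np.random.Generator,
    max_iter: int, tol: float,
) -> tuple[np.ndarray, list[float]]:
    """Factorize multinomial resamples; return pooled L1-normalized profiles
    and per-resample Frobenius reconstruction errors."""
    profiles = []
    frob_errors = []
    totals = V.sum(axis=1).astype(int)
    probs = V / V.sum(axis=1, keepdims=True)
    for _ in range(n_resamples):
        Vb = np.vstack([
            rng.multinomial(totals[i], probs[i]) for i in range(V.shape[0])
        ]).astype(float)
        Vb[Vb.sum(axis=1) == 0, 0] = 1.0  # guard: keep rows non-zero
        # deterministic structured init: resampling noise, not restart noise,
        # is what the stability estimate should measure
        model = NMF(
            n_components=k, init="nndsvda", solver="mu",
            beta_loss="kullback-leibler", max_iter=max_iter, tol=tol,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = model.fit_transform(Vb)
        H = model.components_
        frob_errors.append(float(np.linalg.norm(Vb - W @ H)))
        Hn = H / H.sum(axis=1, keepdims=True)
        profiles.append(Hn)
    return np.vstack(profiles), frob_errors


def stability_analysis(
    spectrum: pd.DataFrame,
    k_range: range | list[int],
    n_resamples: int = 30,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> pd.DataFrame:
    """Bootstrap signature stability and reconstruction error per candidate rank.

    Per rank k: each sample's channel counts are multinomially resampled with
    the sample's total, the resample is factorized, and all resampled profile
    vectors are pooled and partitioned into k clusters by cosine distance
    (spherical k-means on L2-normalized vectors). Stability is the mean cosine
    silhouette over the pooled vectors (for k = 1, the mean pairwise cosine
    similarity); reconstruction error is the median Frobenius error of the
    resample fits. Returns a frame indexed by k with columns ``stability`` and
    ``reconstruction_error`` (stability NaN if a cluster comes out empty).
    """
    V = _check_spectrum(spectrum)
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_range:
        pooled, frob = _pooled_resample_profiles(V, k, n_resamples, rng, max_iter, tol)
        err = float(np.median(frob))
        unit = pooled / np.linalg.norm(pooled, axis=1, keepdims=True)
        if k == 1:
            sims = unit @ unit.T
            n = len(unit)
            stab = float((sims.sum() - n) / (n * (n - 1))) if n > 1 else 1.0
        else:
            km = KMeans(n_clusters=k, n_init=10,
                        random_state=int(rng.integers(0, 2**31 - 1)))
            labels = km.fit_predict(unit)
            if len(np.unique(labels)) < k:
                stab = float("nan")
            else:
                stab = float(silhouette_score(pooled, labels, metric="cosine"))
        rows.append((k, stab, err))
    return pd.DataFrame(rows, columns=["k", "stability", "reconstruction_error"]).set_index("k")


def select_rank(diagnostics: pd.DataFrame) -> int:
    """Pick the rank maximizing stability(k) - error(k)/error(k_min).

    ``diagnostics`` is the output of :func:`stability_analysis`. Ties break
    toward the smaller rank; ranks with missing stability are skipped. The
    full table remains available for manual override.
    """
    valid = diagnostics.dropna(subset=["stability"])
    if valid.empty:
        raise ValueError("no candidate rank has valid diagnostics")
    if len(valid) == 1:
        return int(valid.index[0])
    err0 = float(valid["reconstruction_error"].loc[valid.index.min()])
    score = valid["stability"] - valid["reconstruction_error"] / err0
    best = score.max()
    return int(score.index[np.isclose(score, best)].min())


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two 96-channel vectors; in [0, 1] for counts."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def assign_to_reference(
    profiles: pd.DataFrame,
    reference: pd.DataFrame,
    min_similarity: float = 0.85,
) -> pd.DataFrame:
    """Label each extracted profile with its most-similar reference signature.

    Both frames must share the same channel convention (identical column
    sets); convert references with :func:`load_reference_signatures`'s
    ``convention='native'`` or :func:`somascape.spectrum.to_native_convention`
    first. Profiles whose best similarity falls below ``min_similarity`` are
    labeled ``unknown``; the runner-up match is reported alongside.
    """
    if set(profiles.columns) != set(reference.columns):
        raise ValueError("profile and reference channel conventions differ")
    reference = reference[profiles.columns]
    rows = []
    for name, prof in profiles.iterrows():
        sims = reference.apply(lambda r: cosine_similarity(prof, r), axis=1).sort_values(
            ascending=False
        )
        best, second = sims.index[0], (sims.index[1] if len(sims) > 1 else None)
        label = sims.index[0] if sims.iloc[0] >= min_similarity else "unknown"
        rows.append((name, label, best, float(sims.iloc[0]), second,
                     float(sims.iloc[1]) if second else float("nan")))
    return pd.DataFrame(
        rows,
        columns=["profile", "assignment", "best_match", "similarity",
                 "runner_up", "runner_up_similarity"],
    ).set_index("profile")


@dataclass
class RefitResult:
    """Constrained per-sample exposure refit against a reference catalogue."""

    sample_id: str
    weights: dict[str, float]
    residual_sse: float
    limit: int = 3
    cutoff: float = 0.15


def refit_exposures(
    sample_spectrum,
    reference: pd.DataFrame,
    sample_id: str = "sample",
    limit: int = 3,
    cutoff: float = 0.15,
    min_improvement: float = 1e-4,
) -> RefitResult:
    """Forward-selection signature refit with NNLS re-optimization.

    Starting from the empty set, repeatedly add the reference signature whose
    inclusion (weights re-fit by non-negative least squares over the selected
    set, then normalized to sum 1) most reduces the SSE against the
    L1-normalized sample spectrum; stop at ``limit`` signatures or when the
    best improvement drops below ``min_improvement``. Weights below ``cutoff``
    are zeroed and the survivors renormalized.
    """
    if reference.empty:
        raise ValueError("empty reference set")
    y = np.asarray(sample_spectrum, dtype=float)
    if y.sum() <= 0:
        raise ValueError("sample has no mutations")
    y = y / y.sum()
    R = reference.to_numpy(dtype=float)
    R = R / R.sum(axis=1, keepdims=True)
    names = list(reference.index)

    def fit_subset(idx: list[int]) -> tuple[np.ndarray, float]:
        A = R[idx].T
        w, _ = nnls(A, y)
        if w.sum() > 0:
            w = w / w.sum()
        sse = float(((A @ w - y) ** 2).sum())
        return w, sse

    selected: list[int] = []
    current_sse = float((y**2).sum())
    current_w = np.array([])
    while len(selected) < limit:
        best_gain, best_idx, best_fit = 0.0, None, None
        for j in range(len(names)):
            if j in selected:
                continue
            w, sse = fit_subset(selected + [j])
            gain = current_sse - sse
            if gain > best_gain:
                best_gain, best_idx, best_fit = gain, j, (w, sse)
        if best_idx is None or best_gain < min_improvement:
            break
        selected.append(best_idx)
        current_w, current_sse = best_fit

    weights = {names[i]: float(w) for i, w in zip(selected, current_w)}
    kept = {n: w for n, w in weights.items() if w >= cutoff}
    if kept:
        total = sum(kept.values())
        kept = {n: w / total for n, w in kept.items()}
        A = R[[names.index(n) for n in kept]].T
        w = np.array(list(kept.values()))
        residual = float(((A @ w - y) ** 2).sum())
    else:
        residual = current_sse
    return RefitResult(sample_id, kept, residual, limit, cutoff)


_REFERENCE_RESOURCE = "reference_signatures_synthetic.tsv"


def load_reference_signatures(
    path: str | Path | None = None,
    convention: str = "cosmic",
) -> pd.DataFrame:
    """Load a reference-signature table (signatures x 96, rows sum to 1).

    Without ``path`` the packaged synthetic stand-in catalogue is loaded:
    stylized S1/S2/S3/S17/U2-like profiles stored in the pyrimidine (COSMIC)
    channel convention — these are constructed profiles for testing and
    simulation, not the published Alexandrov tables. User tables are TSV with
    a ``channel`` column (either convention's labels) and one column per
    signature; channel labels determine the convention automatically.

    ``convention``: return the table in ``'cosmic'`` (pyrimidine) or
    ``'native'`` (A/C-reference) channel order.
    """
    if path is None:
        ref = resources.files("somascape") / "data" / _REFERENCE_RESOURCE
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if "channel" not in df.columns:
        raise ValueError("reference table needs a 'channel' column")
    df = df.set_index("channel").T  # signatures x channels
    cols = set(df.columns)
    if cols == set(COSMIC_CHANNELS):
        df = df[COSMIC_CHANNELS]
        in_cosmic = True
    elif cols == set(NATIVE_CHANNELS):
        df = df[NATIVE_CHANNELS]
        in_cosmic = False
    else:
        raise ValueError("channel labels match neither convention")
    if convention == "cosmic" and not in_cosmic:
        from .spectrum import to_cosmic_convention

        df = to_cosmic_convention(df)
    elif convention == "native" and in_cosmic:
        df = to_native_convention(df)
    elif convention not in ("cosmic", "native"):
        raise ValueError("convention must be 'cosmic' or 'native'")
    df = df.div(df.sum(axis=1), axis=0)
    return df
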