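"""Genetic-ancestry inference.

The stage harmonizes study and reference genotypes (allele-swap and
strand-flip correction, ambiguous-variant removal, pooled MAF and missingness
filters), thins variants by linkage disequilibrium, runs a joint PCA with
allele-frequency (Patterson) standardization, expresses each study sample's
position in PC space as a non-negative mixture of reference-group centroids
(NNLS), applies the >5%-other-ancestry exclusion filter, and estimates the
binned / loess-smoothed probability-of-self-identification curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls
from sklearn.utils.extmath import randomized_svd
import statsmodels.api as sm

from .exceptions import InputError
from .genotypes import COMPLEMENT, GenotypeMatrix, VARIANT_COLUMNS

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

# Exact SVD below this min-dimension; seeded randomized SVD above.
_EXACT_SVD_LIMIT = 1024


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _match_alleles(ref0, alt0, ref, alt):
    """How do (ref, alt) relate to the canonical (ref0, alt0)?

    Returns 'same', 'swap' (ref/alt exchanged; dosage reflects d -> 2-d),
    'flip' (opposite strand), 'flip_swap', or None when irreconcilable.
    """
    if (ref, alt) == (ref0, alt0):
        return "same"
    if (ref, alt) == (alt0, ref0):
        return "swap"
    fr, fa = COMPLEMENT[ref], COMPLEMENT[alt]
    if (fr, fa) == (ref0, alt0):
        return "flip"
    if (fr, fa) == (alt0, ref0):
        return "flip_swap"
    return None


def harmonize_variants(datasets, maf_min: float = 0.01,
                       miss_max: float = 0.05) -> GenotypeMatrix:
    """Merge genotype datasets over the variants present in all of them.

    Variants are matched on (chromosome, position) with the first dataset's
    ref/alt orientation as canonical. Allele-swapped records are recoded by
    dosage reflection, strand-flipped records are re-complemented, and
    strand-ambiguous (A/T, C/G) variants are always dropped. Variants with
    pooled MAF <= ``maf_min`` or missingness >= ``miss_max`` are removed.
    Irreconcilable records drop the variant with a logged reason code rather
    than aborting. Identifiers are rewritten as chrom:pos:ref:alt, and the
    merged samples are the concatenation of all input sample sets.
    """
    if len(datasets) < 2:
        raise InputError("harmonize_variants needs >= 2 datasets")
    for d in datasets:
        if d.n_variants == 0 or d.n_samples == 0:
            raise InputError("harmonize_variants: empty dataset")
    first = datasets[0]
    keys = [dict(zip(zip(d.variants["chrom"], d.variants["pos"]), range(d.n_variants)))
            for d in datasets]
    drop_reasons: dict = {}
    kept_rows, kept_cols = [], []  # variant metadata, per-dataset column indices+action
    for j0 in range(first.n_variants):
        rec = first.variants.iloc[j0]
        key = (rec["chrom"], rec["pos"])
        if any(key not in k for k in keys[1:]):
            drop_reasons[key] = "not_shared"
            continue
        if (rec["ref"], rec["alt"]) in AMBIGUOUS_PAIRS:
            drop_reasons[key] = "strand_ambiguous"
            continue
        actions = [("same", j0)]
        ok = True
        for d, kmap in zip(datasets[1:], keys[1:]):
            j = kmap[key]
            other = d.variants.iloc[j]
            if (other["ref"], other["alt"]) in AMBIGUOUS_PAIRS:
                drop_reasons[key] = "strand_ambiguous"
                ok = False
                break
            m = _match_alleles(rec["ref"], rec["alt"], other["ref"], other["alt"])
            if m is None:
                drop_reasons[key] = "allele_mismatch"
                ok = False
                break
            actions.append((m, j))
        if ok:
            kept_rows.append(rec)
            kept_cols.append(actions)
    if drop_reasons:
        logger.info("harmonize_variants dropped %d variants: %s",
                    len(drop_reasons),
                    pd.Series(list(drop_reasons.values())).value_counts().to_dict())
    if not kept_rows:
        raise InputError("harmonize_variants: no variants shared across datasets")

    blocks = []
    for d_idx, d in enumerate(datasets):
        cols = np.empty((d.n_samples, len(kept_cols)))
        for out_j, actions in enumerate(kept_cols):
            action, j = actions[d_idx]
            col = d.dosages[:, j]
            if action in ("swap", "flip_swap"):
                col = 2.0 - col
            cols[:, out_j] = col
        blocks.append(cols)
    dosages = np.vstack(blocks)
    variants = pd.DataFrame(kept_rows).reset_index(drop=True)
    variants["id"] = [f"{c}:{p}:{r}:{a}" for c, p, r, a in
                      zip(variants["chrom"], variants["pos"],
                          variants["ref"], variants["alt"])]
    merged = GenotypeMatrix(
        np.concatenate([d.sample_ids for d in datasets]),
        variants[VARIANT_COLUMNS], dosages,
    )
    maf = merged.maf()
    miss = merged.missingness()
    keep = (maf > maf_min) & (miss < miss_max)
    n_filt = int((~keep).sum())
    if n_filt:
        logger.info("harmonize_variants removed %d variants by MAF/missingness", n_filt)
    order = np.lexsort((merged.variants["pos"].to_numpy(),
                        merged.variants["chrom"].to_numpy()))
    order = order[keep.astype(bool)[order]]
    return merged.take_variants(order)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(g: GenotypeMatrix, window: int = 50, step: int = 5,
             r2_max: float = 0.1) -> GenotypeMatrix:
    """Sliding-window LD pruning of dosage correlations.

    Within each window of ``window`` variants (advanced by ``step``), every
    pair with squared Pearson correlation > ``r2_max`` loses the variant with
    the lower pooled MAF (ties drop the later position). Monomorphic variants
    are kept but never counted as correlated. Windows are defined over the
    input variant sequence, so re-pruning the output removes nothing as long
    as correlations beyond the original window span stay below threshold.
    """
    if window < 2:
        raise InputError("window must be >= 2")
    if not 0.0 < r2_max < 1.0:
        raise InputError("r2_max must lie in (0, 1)")
    X = g.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    poly = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(poly[None, :], X / np.where(sd > 0, sd, 1.0), 0.0)
    maf = g.maf()
    pos = g.variants["pos"].to_numpy()
    n, m = Z.shape
    keep = np.ones(m, dtype=bool)
    for start in range(0, max(m - 1, 1), step):
        idx = np.arange(start, min(start + window, m))
        idx = idx[keep[idx] & poly[idx]]
        if len(idx) < 2:
            if start + window >= m:
                break
            continue
        R = (Z[:, idx].T @ Z[:, idx]) / n
        r2 = R**2
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if not keep[idx[b]]:
                    continue
                if r2[a, b] > r2_max:
                    ia, ib = idx[a], idx[b]
                    if maf[ia] < maf[ib]:
                        drop = ia
                    elif maf[ib] < maf[ia]:
                        drop = ib
                    else:
                        drop = ia if pos[ia] > pos[ib] else ib
                    keep[drop] = False
                    if drop == ia:
                        break
        if start + window >= m:
            break
    return g.take_variants(np.nonzero(keep)[0])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCACoordinates:
    sample_ids: np.ndarray
    scores: np.ndarray              # (n_samples, n_components)
    explained_variance: np.ndarray  # per component
    n_components: int

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores,
                          columns=[f"PC{i+1}" for i in range(self.n_components)])
        df.insert(0, "sample_id", self.sample_ids)
        return df


def run_pca(g: GenotypeMatrix, n_components: int = 10,
            random_state: int = 0) -> PCACoordinates:
    """PCA of allele-frequency-standardized dosages.

    Missing dosages are mean-imputed; each variant is centered at 2p and
    scaled by sqrt(2p(1-p)) (Patterson convention); monomorphic variants are
    dropped. Scores are the projections onto the top right-singular
    directions; the sign convention forces each component's largest-magnitude
    variant loading positive. Small instances use an exact LAPACK SVD, large
    ones a seeded randomized SVD.
    """
    if g.n_samples < 2 or g.n_variants < 2:
        raise InputError("run_pca needs at least 2 samples and 2 variants")
    if n_components > min(g.n_samples, g.n_variants):
        raise InputError("n_components exceeds min(n_samples, n_variants)")
    X = g.dosages.copy()
    nan_mask = np.isnan(X)
    freq = np.nanmean(X, axis=0) / 2.0
    if nan_mask.any():
        X[nan_mask] = np.take(2.0 * freq, np.nonzero(nan_mask)[1])
    poly = (freq > 0) & (freq < 1)
    X = X[:, poly]
    p = freq[poly]
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    if min(Z.shape) <= _EXACT_SVD_LIMIT:
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    else:
        U, s, Vt = randomized_svd(Z, n_components=n_components,
                                  n_oversamples=10, n_iter=7,
                                  random_state=random_state)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * s
    return PCACoordinates(
        sample_ids=g.sample_ids.copy(),
        scores=scores,
        explained_variance=s**2 / (g.n_samples - 1),
        n_components=n_components,
    )


# ---------------------------------------------------------------------------
# NNLS ancestry fractions
# ---------------------------------------------------------------------------

@dataclass
class AncestryEstimate:
    sample_ids: np.ndarray
    fractions: pd.DataFrame   # one column per ancestry group, rows sum to 1
    groups: list
    flagged: np.ndarray       # True where the NNLS solution was all-zero

    def frame(self) -> pd.DataFrame:
        df = self.fractions.copy()
        df.insert(0, "sample_id", self.sample_ids)
        df["flagged"] = self.flagged
        return df


def infer_ancestry_nnls(pcs: PCACoordinates, reference_labels) -> AncestryEstimate:
    """Assign ancestry fractions by NNLS against reference-group centroids.

    ``reference_labels`` maps reference sample id -> ancestry group (dict or
    Series); samples not in the mapping are treated as study samples. Each
    study sample's PC vector x is decomposed as min ||x - C w||, w >= 0, with
    C's columns the group centroid PC vectors; fractions are w / sum(w).
    All-zero solutions are flagged (fractions NaN) rather than aborting.

    Because PCA centers scores at the pooled mean, with exactly two groups the
    centroids are anti-parallel through the origin and the weight ratio of a
    plain NNLS is not identified (any point on the centroid segment admits a
    one-parameter family of non-negative solutions). The system is therefore
    augmented with a constant row — a soft affine (sum-to-one) constraint —
    which uniquely resolves mixtures of the group centroids while leaving
    well-posed many-group geometries essentially unchanged.
    """
    labels = pd.Series(reference_labels)
    groups = sorted(labels.unique())
    sample_index = pd.Index(pcs.sample_ids)
    C = np.empty((pcs.n_components, len(groups)))
    for k, gname in enumerate(groups):
        ref_ids = labels.index[labels == gname]
        locs = sample_index.get_indexer(ref_ids)
        locs = locs[locs >= 0]
        if len(locs) < 2:
            raise InputError(f"ancestry group {gname!r} has fewer than 2 reference samples")
        C[:, k] = pcs.scores[locs].mean(axis=0)
    is_ref = sample_index.isin(labels.index)
    study_idx = np.nonzero(~is_ref)[0]
    frac = np.full((len(study_idx), len(groups)), np.nan)
    flagged = np.zeros(len(study_idx), dtype=bool)
    kappa = float(np.mean(np.linalg.norm(C, axis=0)))
    if kappa == 0.0:
        kappa = 1.0
    C_aug = np.vstack([C, np.full(len(groups), kappa)])
    for i, loc in enumerate(study_idx):
        x_aug = np.concatenate([pcs.scores[loc], [kappa]])
        w, _ = _nnls(C_aug, x_aug)
        tot = w.sum()
        if tot <= 0:
            flagged[i] = True
        else:
            frac[i] = w / tot
    return AncestryEstimate(
        sample_ids=pcs.sample_ids[study_idx],
        fractions=pd.DataFrame(frac, columns=groups),
        groups=groups,
        flagged=flagged,
    )


def apply_ancestry_filter(est: AncestryEstimate, allowed_groups,
                          max_other: float = 0.05) -> np.ndarray:
    """Sample ids whose ancestry mass outside ``allowed_groups`` is <= max_other.

    The boundary is inclusive: exactly ``max_other`` other ancestry is
    retained (the exclusion rule reads "strictly greater"). Flagged samples
    (undefined fractions) are excluded.
    """
    allowed = set(allowed_groups)
    if allowed - set(est.groups):
        raise InputError(f"allowed groups {sorted(allowed - set(est.groups))} "
                         "not present in the estimate")
    if not 0.0 <= max_other <= 1.0:
        raise InputError("max_other must lie in [0, 1]")
    other_cols = [g for g in est.groups if g not in allowed]
    other = est.fractions[other_cols].sum(axis=1).to_numpy() if other_cols \
        else np.zeros(len(est.sample_ids))
    ok = (other <= max_other) & ~est.flagged
    return est.sample_ids[ok]


# ---------------------------------------------------------------------------
# Self-identification probability curve
# ---------------------------------------------------------------------------

@dataclass
class SelfIdCurve:
    bin_edges: np.ndarray          # n_bins + 1 edges over [0, 1]
    midpoints: np.ndarray
    p_black: np.ndarray            # NaN for empty bins
    p_white: np.ndarray
    counts: np.ndarray
    smoothed_p_black: np.ndarray   # defined at non-empty midpoints, NaN elsewhere
    smoothed_p_white: np.ndarray
    crossover_estimate: float      # NaN when the smoothed curves never cross

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "midpoint": self.midpoints, "n": self.counts,
            "p_black": self.p_black, "p_white": self.p_white,
            "smoothed_p_black": self.smoothed_p_black,
            "smoothed_p_white": self.smoothed_p_white,
        })


def _loess(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Locally weighted linear regression (tricube weights), no robustifying."""
    if len(x) < 3:
        return y.copy()
    fitted = sm.nonparametric.lowess(y, x, frac=span, it=0, return_sorted=False)
    return np.asarray(fitted)


def selfid_probability_curve(theta_hat, ethnicity, n_bins: int = 100,
                             span: float = 0.75) -> SelfIdCurve:
    """Binned + loess-smoothed probability of self-identifying Black / White.

    Ancestry fractions are binned into ``n_bins`` equal-width bins over
    [0, 1]; per non-empty bin the probabilities are simple label frequencies.
    Loess smoothing runs over the non-empty bin midpoints. The crossover
    estimate is the smallest midpoint where the smoothed Black curve meets or
    exceeds the smoothed White curve (NaN when there is no crossing).
    """
    if n_bins < 2:
        raise InputError("n_bins must be >= 2")
    theta = np.asarray(theta_hat, dtype=float)
    eth = np.asarray(ethnicity, dtype=object)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mids = (edges[:-1] + edges[1:]) / 2.0
    bins = np.clip(np.digitize(theta, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    blacks = np.bincount(bins, weights=(eth == "Black").astype(float),
                         minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_black = np.where(counts > 0, blacks / counts, np.nan)
    p_white = np.where(counts > 0, 1.0 - p_black, np.nan)
    defined = counts > 0
    sm_black = np.full(n_bins, np.nan)
    sm_white = np.full(n_bins, np.nan)
    if defined.sum() >= 1:
        sm_black[defined] = np.clip(_loess(mids[defined], p_black[defined], span), 0, 1)
        sm_white[defined] = np.clip(_loess(mids[defined], p_white[defined], span), 0, 1)
    crossing = defined & (sm_black >= sm_white)
    crossover = float(mids[np.nonzero(crossing)[0][0]]) if crossing.any() else float("nan")
    return SelfIdCurve(
        bin_edges=edges, midpoints=mids, p_black=p_black, p_white=p_white,
        counts=counts, smoothed_p_black=sm_black, smoothed_p_white=sm_white,
        crossover_estimate=crossover,
    )
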