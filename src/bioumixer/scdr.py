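"""Supervised contrastive learning for deep regression (SCDR).

Biomass regression from canopy images is imbalanced: most plots carry
mid-range mass and the tails are sparse.  SCDR adds a contrastive term to the
regression objective so that images with similar biomass end up close in the
encoder's feature space and images with dissimilar biomass are pushed apart —
but only when the model currently confuses them (similar predictions despite
dissimilar labels).  Concretely, every training image is augmented into two
views; a pair of views is

* **positive**   if their labels differ by at most ``omega``,
* **negative**   if their labels differ by more than ``omega`` while their
  current predictions differ by at most ``omega``,
* **unpaired**   otherwise.

A view with at least one negative is an *anchor*.  Its loss is

    L_j = -log [ (1/N+_j) Σ_{i∈P+} e^{v_j·v_i/τ}
                 / ( Σ_{p∈P+} e^{v_j·v_p/τ} + Σ_{q∈P-} S_{j,q} e^{v_j·v_q/τ} ) ]

with temperature ``tau`` and a per-negative *thrust* weight

    S_{j,q} = min( eta / (Sim_l(y_j, y_q) · Sim_f(v_j, v_q)), S_max )

where ``Sim_l = exp(-|Δy|/σ_l)`` and ``Sim_f = max((1+cosθ)/2, ε_f)``: a
negative pair whose labels are far apart gets a stronger push, while high
feature similarity damps the push and with it the influence of mislabelled
pairs.  Non-anchors contribute exactly zero; the batch loss averages over all
2N views, and the total objective is ``alpha·L_reg + beta·L_scdr``.

Pairing decisions and thrust weights are computed from *detached* predictions
and embeddings; gradients flow only through the exp(v·v/τ) terms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

# status codes of the pair matrix
SELF, POSITIVE, NEGATIVE, UNPAIRED = 0, 1, 2, 3


# --------------------------------------------------------------------- types
@dataclass
class RegressionSample:
    """One RGB image (H×W×3, values in [0,1]) with its biomass label in grams."""

    image: np.ndarray
    label: float
    name: str = ""

    def __post_init__(self):
        if self.label <= 0:
            raise ValueError(f"biomass label must be positive, got {self.label}")
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be H×W×3, got shape {self.image.shape}")


@dataclass
class AugmentedBatch:
    """2N augmented views; views 2k and 2k+1 share source k and its label."""

    views: np.ndarray        # (2N, 3, H, W), standardized, channel-first
    labels: np.ndarray       # (2N,)
    source_index: np.ndarray  # (2N,)

    @property
    def n_views(self) -> int:
        return self.views.shape[0]


@dataclass
class SCDRConfig:
    """Hyperparameters of the SCDR objective.

    ``omega`` and ``sigma_l`` carry label units (grams); when left ``None``
    the trainer sets them from the training-label standard deviation
    (10% and 25% of it respectively).
    """

    tau: float = 0.2
    eta: float = 0.01
    alpha: float = 1.0
    beta: float = 3.0
    omega: float | None = None
    sigma_l: float | None = None
    eps_f: float = 0.05
    s_max: float = 100.0
    normalize_embeddings: bool = True
    regression_kind: str = "focal_l1"
    focal_gamma: float = 1.0
    focal_p: float = 1.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("temperature tau must be > 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights alpha, beta must be >= 0")
        if self.omega is not None and self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.sigma_l is not None and self.sigma_l <= 0:
            raise ValueError("sigma_l must be > 0")
        if not 0.0 < self.eps_f < 1.0:
            raise ValueError("eps_f must be in (0, 1)")
        if self.s_max <= 0:
            raise ValueError("s_max must be > 0")
        if self.regression_kind not in ("l1", "focal_l1"):
            raise ValueError(f"unknown regression loss kind {self.regression_kind!r}")

    def resolved(self, label_std: float) -> "SCDRConfig":
        """Fill data-dependent defaults from the training-label spread."""
        return replace(
            self,
            omega=self.omega if self.omega is not None else 0.1 * label_std,
            sigma_l=self.sigma_l if self.sigma_l is not None else 0.25 * label_std,
        )


@dataclass
class PairAssignment:
    status: np.ndarray              # (2N, 2N) int8 over {SELF, POSITIVE, NEGATIVE, UNPAIRED}
    positives: list                 # per-view index arrays P+
    negatives: list                 # per-view index arrays P-
    anchor_flags: np.ndarray        # (2N,) bool, True iff |P-| > 0


@dataclass
class LossBreakdown:
    per_anchor: np.ndarray          # (2N,) detached per-view SCDR losses
    l_scdr: float
    l_reg: float
    l_sum: float
    anchor_fraction: float = 0.0


# -------------------------------------------------------------- augmentation
@dataclass
class AugmentSpec:
    """The training augmentation set: crop, flips, colour-contrast jitter,
    then per-channel standardization (the normalization step)."""

    out_size: int = 64
    crop_scale: tuple = (0.7, 1.0)
    hflip_p: float = 0.5
    vflip_p: float = 0.5
    contrast: tuple = (0.75, 1.25)
    mean: tuple = (0.5, 0.5, 0.5)
    std: tuple = (0.25, 0.25, 0.25)


def _random_view(img: np.ndarray, spec: AugmentSpec, rng: np.random.Generator) -> np.ndarray:
    """Sample one augmentation t(·) and apply it; returns standardized CHW."""
    H, W, _ = img.shape
    # random crop of a random scale, resized back to out_size (nearest)
    scale = rng.uniform(*spec.crop_scale)
    ch = max(1, int(round(H * scale)))
    cw = max(1, int(round(W * scale)))
    top = rng.integers(0, H - ch + 1)
    left = rng.integers(0, W - cw + 1)
    crop = img[top : top + ch, left : left + cw]
    rows = np.clip((np.arange(spec.out_size) + 0.5) * ch / spec.out_size, 0, ch - 1).astype(int)
    cols = np.clip((np.arange(spec.out_size) + 0.5) * cw / spec.out_size, 0, cw - 1).astype(int)
    view = crop[rows][:, cols]
    if rng.random() < spec.hflip_p:
        view = view[:, ::-1]
    if rng.random() < spec.vflip_p:
        view = view[::-1]
    c = rng.uniform(*spec.contrast)
    view = np.clip((view - view.mean()) * c + view.mean(), 0.0, 1.0)
    return standardize(view, spec)


def standardize(img_hwc: np.ndarray, spec: AugmentSpec) -> np.ndarray:
    """[0,1] HWC → standardized CHW float32 (the deterministic eval transform,
    combined with a centre resize when sizes differ)."""
    H, W, _ = img_hwc.shape
    if (H, W) != (spec.out_size, spec.out_size):
        rows = np.clip((np.arange(spec.out_size) + 0.5) * H / spec.out_size, 0, H - 1).astype(int)
        cols = np.clip((np.arange(spec.out_size) + 0.5) * W / spec.out_size, 0, W - 1).astype(int)
        img_hwc = img_hwc[rows][:, cols]
    out = (img_hwc - np.asarray(spec.mean)) / np.asarray(spec.std)
    return np.ascontiguousarray(out.transpose(2, 0, 1), dtype=np.float32)


def make_augmented_batch(samples, transform_spec: AugmentSpec, rng_seed: int) -> AugmentedBatch:
    """Two independently augmented views per sample with duplicated labels.

    View ``2k`` is ``t(x_k)`` and view ``2k+1`` is ``t'(x_k)`` where t, t' are
    independently sampled from the augmentation set; the label of an
    augmented view equals its source label.  Deterministic for a fixed seed.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("make_augmented_batch: empty sample list")
    rng = np.random.default_rng(rng_seed)
    views, labels, sources = [], [], []
    for k, s in enumerate(samples):
        H, W, _ = s.image.shape
        if H < transform_spec.out_size or W < transform_spec.out_size:
            raise ValueError(
                f"image {s.name or k} ({H}×{W}) smaller than crop size {transform_spec.out_size}"
            )
        for _ in range(2):
            views.append(_random_view(s.image, transform_spec, rng))
            labels.append(s.label)
            sources.append(k)
    return AugmentedBatch(
        views=np.stack(views),
        labels=np.asarray(labels, dtype=np.float64),
        source_index=np.asarray(sources, dtype=np.int64),
    )


# ------------------------------------------------------------------- pairing
def classify_pairs(labels: np.ndarray, predictions: np.ndarray, omega: float) -> PairAssignment:
    """Positive / negative / unpaired status for every view pair.

    Pair (i, j), i≠j is positive iff |y_i − y_j| ≤ ω; negative iff
    |y_i − y_j| > ω and |ŷ_i − ŷ_j| ≤ ω; unpaired otherwise.  A view is an
    anchor iff it has at least one negative.
    """
    labels = np.asarray(labels, dtype=np.float64)
    predictions = np.asarray(predictions, dtype=np.float64)
    if labels.shape != predictions.shape or labels.ndim != 1:
        raise ValueError("labels and predictions must be equal-length 1-D arrays")
    n = labels.size
    if n % 2 != 0:
        raise ValueError(f"augmented batch must have an even number of views, got {n}")
    if np.isnan(labels).any() or np.isnan(predictions).any():
        raise ValueError("NaN in labels or predictions")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    dy = np.abs(labels[:, None] - labels[None, :])
    dp = np.abs(predictions[:, None] - predictions[None, :])
    off = ~np.eye(n, dtype=bool)
    status = np.full((n, n), UNPAIRED, dtype=np.int8)
    status[(dy <= omega) & off] = POSITIVE
    status[(dy > omega) & (dp <= omega) & off] = NEGATIVE
    np.fill_diagonal(status, SELF)
    positives = [np.flatnonzero(status[j] == POSITIVE) for j in range(n)]
    negatives = [np.flatnonzero(status[j] == NEGATIVE) for j in range(n)]
    anchors = np.array([len(q) > 0 for q in negatives])
    return PairAssignment(status, positives, negatives, anchors)


# -------------------------------------------------------------- similarities
def label_similarity(y_a: float, y_b: float, sigma_l: float) -> float:
    """Exponential label kernel exp(−|y_a − y_b|/σ_l) ∈ (0, 1]."""
    if sigma_l <= 0:
        raise ValueError("sigma_l must be > 0")
    return float(np.exp(-abs(float(y_a) - float(y_b)) / sigma_l))


def feature_similarity(u: np.ndarray, v: np.ndarray, eps_f: float) -> float:
    """Shifted cosine similarity max((1 + cosθ)/2, ε_f) ∈ [ε_f, 1]."""
    if not 0.0 < eps_f < 1.0:
        raise ValueError("eps_f must be in (0, 1)")
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("feature_similarity: zero vector")
    cos = float(u @ v) / (nu * nv)
    return max((1.0 + cos) / 2.0, eps_f)


def thrust_weight(eta: float, sim_l: float, sim_f: float, s_max: float) -> float:
    """Thrust S = min(η/(Sim_l·Sim_f), S_max): proportional to η, inversely
    proportional to both similarities, capped at S_max."""
    if eta < 0:
        raise ValueError("eta must be >= 0")
    if s_max <= 0:
        raise ValueError("s_max must be > 0")
    for s in (sim_l, sim_f):
        if not 0.0 < s <= 1.0:
            raise ValueError(f"similarity {s} outside (0, 1]")
    if eta == 0.0:
        return 0.0
    return min(eta / (sim_l * sim_f), s_max)


def thrust_matrix(labels: np.ndarray, embeddings: np.ndarray, pairs: PairAssignment,
                  config: SCDRConfig) -> np.ndarray:
    """Dense (2N, 2N) thrust matrix; zero wherever (j, q) is not a negative pair."""
    if config.sigma_l is None:
        raise ValueError("sigma_l unset; call SCDRConfig.resolved() first")
    n = len(labels)
    S = np.zeros((n, n), dtype=np.float64)
    if config.eta == 0.0:
        return S
    emb = np.asarray(embeddings, dtype=np.float64)
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    unit = emb / np.maximum(norms, 1e-12)
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    sim_f = np.maximum((1.0 + cos) / 2.0, config.eps_f)
    dy = np.abs(np.asarray(labels)[:, None] - np.asarray(labels)[None, :])
    sim_l = np.exp(-dy / config.sigma_l)
    neg = pairs.status == NEGATIVE
    S[neg] = np.minimum(config.eta / (sim_l[neg] * sim_f[neg]), config.s_max)
    return S


# -------------------------------------------------------------------- losses
def _normalize_rows(v: Tensor) -> Tensor:
    norm = ad.sqrt((v**2).sum(axis=1, keepdims=True) + 1e-12)
    return v / norm


def scdr_anchor_loss(j: int, embeddings: np.ndarray, pairs: PairAssignment,
                     thrust: np.ndarray, tau: float) -> float:
    """Per-view contrastive loss (plain numpy, non-differentiable form).

    Returns 0 for non-anchors.  The batched, differentiable version is
    :func:`scdr_batch_loss`; this scalar form serves the API and diagnostics.
    """
    if tau <= 0:
        raise ValueError("temperature tau must be > 0")
    if not pairs.anchor_flags[j]:
        return 0.0
    pos = pairs.positives[j]
    neg = pairs.negatives[j]
    if len(pos) == 0:
        raise RuntimeError("anchor without positives violates the sibling guarantee")
    v = np.asarray(embeddings, dtype=np.float64)
    logits = v @ v[j] / tau
    num = np.exp(logits[pos]).mean()
    den = np.exp(logits[pos]).sum() + (thrust[j, neg] * np.exp(logits[neg])).sum()
    return float(-np.log(num / den))


def scdr_batch_loss(embeddings: Tensor, labels: np.ndarray, predictions: np.ndarray,
                    config: SCDRConfig):
    """Vectorized L_SCDR over all 2N views.

    Returns ``(l_scdr: Tensor, per_anchor: np.ndarray, pairs: PairAssignment)``
    where ``l_scdr`` is the mean of the per-view losses (non-anchors
    contribute 0) and carries gradients with respect to ``embeddings``.
    """
    if config.omega is None:
        raise ValueError("omega unset; call SCDRConfig.resolved() first")
    emb = embeddings if isinstance(embeddings, Tensor) else Tensor(embeddings)
    if config.normalize_embeddings:
        emb = _normalize_rows(emb)
    n = emb.shape[0]
    pairs = classify_pairs(labels, predictions, config.omega)
    anchors = pairs.anchor_flags
    if not anchors.any():
        zero = (emb * 0.0).sum()  # keeps the graph connected with zero gradient
        return zero, np.zeros(n), pairs

    S = thrust_matrix(labels, emb.data, pairs, config)
    logits = (emb @ emb.transpose((1, 0))) * (1.0 / config.tau)

    pos_mask = (pairs.status == POSITIVE).astype(np.float64)
    used = np.maximum(pos_mask, S > 0)
    # per-row stabiliser over the entries that actually appear in Eq. (1)
    m = np.where(used > 0, logits.data, -np.inf).max(axis=1)
    m = np.where(np.isfinite(m), m, 0.0)
    E = ad.exp(logits - Tensor(m[:, None]))

    n_pos = pos_mask.sum(axis=1)
    if np.any(anchors & (n_pos == 0)):
        raise RuntimeError("anchor without positives violates the sibling guarantee")
    pos_sum = (E * Tensor(pos_mask)).sum(axis=1)
    neg_sum = (E * Tensor(S)).sum(axis=1)
    # keep logs finite on positive-free rows; those rows are never anchors
    # (checked above) so the anchor mask zeroes them out exactly
    guard = Tensor((n_pos == 0).astype(np.float64))
    pos_sum = pos_sum + guard
    # L_j = log N+_j + log(pos_sum + neg_sum) − log(pos_sum), anchors only
    per_view = ad.log(pos_sum + neg_sum) - ad.log(pos_sum) + Tensor(np.log(np.maximum(n_pos, 1)))
    amask = anchors.astype(np.float64)
    l_scdr = (per_view * Tensor(amask)).sum() * (1.0 / n)
    per_anchor = per_view.data * amask
    return l_scdr, per_anchor, pairs


def regression_loss(predictions, labels, kind: str = "l1",
                    focal_gamma: float = 1.0, focal_p: float = 1.0) -> Tensor:
    """Regression loss: plain MAE (``l1``) or its focal variant
    mean(sigmoid(γ·|e|)^p · |e|) that up-weights large errors."""
    if kind not in ("l1", "focal_l1"):
        raise ValueError(f"unknown regression loss kind {kind!r}")
    pred = predictions if isinstance(predictions, Tensor) else Tensor(np.asarray(predictions, dtype=np.float64))
    err = ad.tabs(pred - Tensor(np.asarray(labels, dtype=np.float64)))
    if kind == "l1":
        return err.mean()
    weight = ad.sigmoid(Tensor(focal_gamma) * err.detach()) ** focal_p
    return (weight * err).mean()


def total_loss(l_reg, l_scdr, alpha: float, beta: float):
    """Weighted total objective α·L_reg + β·L_SCDR."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    return alpha * l_reg + beta * l_scdr


def scdr_total_loss(embeddings: Tensor, predictions: Tensor, labels: np.ndarray,
                    raw_predictions: np.ndarray, raw_labels: np.ndarray,
                    config: SCDRConfig):
    """Full Eq.-(4) objective for one augmented batch.

    ``labels``/``predictions`` are on the (possibly normalized) regression
    scale; ``raw_*`` are in label units and drive the ω-pairing and thrust.
    Returns ``(l_sum: Tensor, LossBreakdown)``.
    """
    l_reg = regression_loss(predictions, labels, config.regression_kind,
                            config.focal_gamma, config.focal_p)
    if config.beta > 0:
        l_scdr, per_anchor, pairs = scdr_batch_loss(embeddings, raw_labels,
                                                    raw_predictions, config)
        anchor_fraction = float(pairs.anchor_flags.mean())
    else:
        l_scdr = Tensor(0.0)
        per_anchor = np.zeros(embeddings.shape[0])
        anchor_fraction = 0.0
    l_sum = total_loss(l_reg, l_scdr, config.alpha, config.beta)
    breakdown = LossBreakdown(
        per_anchor=per_anchor,
        l_scdr=float(l_scdr.data),
        l_reg=float(l_reg.data),
        l_sum=float(l_sum.data),
        anchor_fraction=anchor_fraction,
    )
    return l_sum, breakdown
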