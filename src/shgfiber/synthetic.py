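"""Synthetic SHG images, two-group cohorts, survival times, and DE tables.

Every downstream stage of the pipeline is exercised against data generated
here, with known ground truth:

* **Fiber images** — curvilinear bright fibers drawn as directionally
  persistent random walks dilated to a sampled width, on a noisy background,
  plus circular non-fibrillar blob confounders that are deliberately excluded
  from the ground-truth mask.
* **Cohorts** — two patient groups (non-recurrent / recurrent) with 6-18
  fields of view per patient and log-normal percent fiber volumes carrying
  separate between-patient and within-patient variance components:

      log(volume_ij) = mu + beta * 1{recurrent} + b_i + eps_ij,
      b_i ~ N(0, sd_between^2),  eps_ij ~ N(0, sd_within^2).

* **Survival** — exponential event times whose hazard is multiplied by a
  specified ratio for patients whose *true* mean volume exceeds the cohort
  median, with independent exponential censoring.
* **DE tables** — null genes with N(0, sd) log2 fold changes and uniform
  p-values, plus planted effect genes; the padj column is Benjamini-Hochberg
  adjusted via :func:`shgfiber.de_panel.benjamini_hochberg`.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_footprint

from .images import DEFAULT_PIXEL_SIZE_UM, FiberMask, ShgImage


@dataclass
class FiberImageParams:
    """Settings for one synthetic SHG field of view.

    When ``target_fraction`` is given, fibers are added until the truth mask
    reaches that volume fraction (``n_fibers`` acts as a hard cap); when it is
    ``None``, exactly ``n_fibers`` fibers are drawn.  Blobs emulate
    non-fibrillar bright structures and never enter the truth mask.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_fibers: int = 400
    target_fraction: float | None = 0.10
    fiber_width_px: float = 3.0
    fiber_length_px: float = 80.0
    persistence: float = 0.9
    n_blobs: int = 0
    blob_radius_px: float = 6.0
    fiber_intensity: float = 200.0
    background_level: float = 10.0
    gaussian_sigma: float = 3.0
    poisson_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 2 or any(s <= 0 for s in self.shape):
            raise ValueError("shape must be two positive dimensions")
        if self.target_fraction is not None and not 0 <= self.target_fraction < 1:
            raise ValueError("target_fraction must lie in [0, 1)")
        if self.n_fibers < 0 or self.n_blobs < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.persistence <= 1:
            raise ValueError("persistence must lie in [0, 1]")
        if self.fiber_width_px >= min(self.shape):
            raise ValueError("fiber width exceeds the image; impossible geometry")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


def _draw_fiber(canvas: np.ndarray, rng: np.random.Generator, params: FiberImageParams) -> None:
    """Rasterise one persistent random-walk fiber onto ``canvas`` (in place)."""
    h, w = canvas.shape
    length = max(3, int(rng.normal(params.fiber_length_px, 0.25 * params.fiber_length_px)))
    width = max(1.0, rng.normal(params.fiber_width_px, 0.25 * params.fiber_width_px))
    y, x = rng.uniform(0, h), rng.uniform(0, w)
    theta = rng.uniform(0, 2 * np.pi)
    wobble = (1.0 - params.persistence) * np.pi / 2
    path = np.zeros_like(canvas, dtype=bool)
    py, px = int(y), int(x)
    for _ in range(length):
        theta += rng.normal(0.0, wobble) if wobble > 0 else 0.0
        y += np.sin(theta)
        x += np.cos(theta)
        ny, nx = int(round(y)), int(round(x))
        ny = min(max(ny, 0), h - 1)
        nx = min(max(nx, 0), w - 1)
        rr, cc = draw_line(py, px, ny, nx)
        path[rr, cc] = True
        py, px = ny, nx
    radius = max(int(round((width - 1) / 2)), 0)
    if radius > 0:
        ys, xs = np.nonzero(path)
        y0 = max(ys.min() - radius, 0)
        y1 = min(ys.max() + radius + 1, h)
        x0 = max(xs.min() - radius, 0)
        x1 = min(xs.max() + radius + 1, w)
        box = ndimage.binary_dilation(path[y0:y1, x0:x1], structure=disk_footprint(radius))
        canvas[y0:y1, x0:x1] |= box
    else:
        canvas |= path


def generate_fiber_image(params: FiberImageParams) -> tuple[ShgImage, FiberMask]:
    """Generate one noisy SHG-like field of view and its ground-truth mask.

    Returns
    -------
    (ShgImage, FiberMask)
        The intensity image (background + fibers + blobs, Poisson shot noise
        and Gaussian read noise) and the exact boolean fiber mask.  Blob
        confounders appear in the image but not in the truth mask.  The same
        parameters and seed yield bit-identical outputs.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    truth = np.zeros((h, w), dtype=bool)

    if params.target_fraction is not None and params.target_fraction > 0:
        target_px = params.target_fraction * truth.size
        drawn = 0
        while truth.sum() < target_px and drawn < params.n_fibers:
            _draw_fiber(truth, rng, params)
            drawn += 1
    else:
        for _ in range(params.n_fibers):
            _draw_fiber(truth, rng, params)

    blobs = np.zeros_like(truth)
    for _ in range(params.n_blobs):
        r = max(1.0, rng.normal(params.blob_radius_px, 0.2 * params.blob_radius_px))
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        rr, cc = draw_disk((cy, cx), r, shape=(h, w))
        blobs[rr, cc] = True

    clean = params.background_level + params.fiber_intensity * (truth | blobs).astype(float)
    if params.gaussian_sigma > 0:
        noisy = clean + rng.normal(0.0, params.gaussian_sigma, size=clean.shape)
    else:
        noisy = clean.copy()
    if params.poisson_scale > 0:
        shot = rng.poisson(np.clip(clean, 0, None) * params.poisson_scale) / params.poisson_scale
        noisy += shot - clean
    noisy = np.clip(noisy, 0, None)

    image = ShgImage(noisy, pixel_size_um=params.pixel_size_um)
    return image, FiberMask(truth, pixel_size_um=params.pixel_size_um)


@dataclass
class CohortParams:
    """Settings for a two-group FOV cohort with variance components.

    ``mu_log`` and the SDs act on the natural-log scale of percent fiber
    volume; ``group_effect_log`` is the additive recurrent-group effect.
    Survival times are exponential with ``base_hazard`` events per unit time,
    multiplied by ``true_hr`` for patients whose true mean volume exceeds the
    cohort median, censored by an independent Exp(``censor_rate``) clock.
    """

    #: patients per group; an int for equal groups or a (non_recurrent,
    #: recurrent) pair for an unbalanced design such as 12 vs 14
    n_patients_per_group: int | tuple[int, int] = 13
    fovs_min: int = 6
    fovs_max: int = 18
    mu_log: float = 0.7
    group_effect_log: float = 0.5
    sd_between: float = 0.5
    sd_within: float = 0.6
    true_hr: float = 2.7
    base_hazard: float = 0.1
    censor_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.group_sizes) < 2:
            raise ValueError("need >= 2 patients per group for downstream statistics")
        if self.fovs_min < 1 or self.fovs_min > self.fovs_max:
            raise ValueError("require 1 <= fovs_min <= fovs_max")
        if self.sd_between < 0 or self.sd_within < 0:
            raise ValueError("variance components must be >= 0")
        if self.true_hr <= 0 or self.base_hazard <= 0:
            raise ValueError("hazards must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")

    @property
    def group_sizes(self) -> tuple[int, int]:
        n = self.n_patients_per_group
        return (n, n) if isinstance(n, int) else (int(n[0]), int(n[1]))


GROUPS = ("non_recurrent", "recurrent")


def generate_cohort(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-FOV percent fiber volumes and per-patient survival.

    Returns
    -------
    (fovs, patients)
        ``fovs``: patient_id, group, fov_id, percent_fiber_volume.
        ``patients``: patient_id, group, mean_volume, n_fov, time, event,
        plus the latent ``true_mean_volume`` used for the hazard split.
    """
    rng = np.random.default_rng(params.seed)
    patient_ids, groups, b_effects, n_fovs = [], [], [], []
    for g_idx, group in enumerate(GROUPS):
        for p in range(params.group_sizes[g_idx]):
            patient_ids.append(f"{'NR' if g_idx == 0 else 'R'}{p + 1:03d}")
            groups.append(group)
            b_effects.append(rng.normal(0.0, params.sd_between))
            n_fovs.append(int(rng.integers(params.fovs_min, params.fovs_max + 1)))

    fov_rows = []
    for pid, group, b, n in zip(patient_ids, groups, b_effects, n_fovs):
        mu = params.mu_log + params.group_effect_log * (group == "recurrent") + b
        logs = mu + rng.normal(0.0, params.sd_within, size=n)
        vols = np.minimum(np.exp(logs), 100.0)
        for k, v in enumerate(vols):
            fov_rows.append((pid, group, f"{pid}_f{k + 1:02d}", float(v)))
    fovs = pd.DataFrame(
        fov_rows, columns=["patient_id", "group", "fov_id", "percent_fiber_volume"]
    )

    true_means = np.exp(
        params.mu_log
        + params.group_effect_log * (np.asarray(groups) == "recurrent")
        + np.asarray(b_effects)
    )
    high = true_means > np.median(true_means)
    hazards = params.base_hazard * np.where(high, params.true_hr, 1.0)
    event_times = rng.exponential(1.0 / hazards)
    if params.censor_rate > 0:
        censor_times = rng.exponential(1.0 / params.censor_rate, size=len(hazards))
    else:
        censor_times = np.full(len(hazards), np.inf)
    times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)

    observed = fovs.groupby("patient_id", sort=False)["percent_fiber_volume"].agg(["mean", "size"])
    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "group": groups,
            "mean_volume": observed["mean"].reindex(patient_ids).to_numpy(),
            "n_fov": observed["size"].reindex(patient_ids).to_numpy(),
            "time": times,
            "event": events,
            "true_mean_volume": true_means,
        }
    )
    return fovs, patients


def generate_de_table(
    n_genes: int,
    planted: list[tuple[str, float]] | None = None,
    null_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a differential-expression result table.

    Null genes get ``log2fc ~ N(0, null_sd)`` and Uniform(0, 1) p-values;
    planted genes carry their stated log2 fold change plus small noise and
    very small p-values.  The ``padj`` column is Benjamini-Hochberg adjusted.
    """
    from .de_panel import benjamini_hochberg

    planted = planted or []
    symbols = [s for s, _ in planted]
    if len(set(symbols)) != len(symbols):
        raise ValueError("duplicate planted gene symbols")
    if n_genes < len(planted):
        raise ValueError("n_genes must cover the planted genes")

    rng = np.random.default_rng(seed)
    n_null = n_genes - len(planted)
    rows = []
    for i, (sym, lfc) in enumerate(planted):
        rows.append((sym, 100000 + i, lfc + rng.normal(0.0, 0.02), 10.0 ** rng.uniform(-15.0, -8.0)))
    for i in range(n_null):
        rows.append((f"NULL{i + 1:05d}", 200000 + i, rng.normal(0.0, null_sd), rng.uniform()))
    table = pd.DataFrame(rows, columns=["symbol", "gene_id", "log2fc", "pvalue"])
    table["padj"] = benjamini_hochberg(table["pvalue"].to_numpy())
    return table


def write_cohort_csv(fovs: pd.DataFrame, patients: pd.DataFrame, fov_path, patient_path) -> None:
    """Write the cohort tables with the standard column layout."""
    fovs[["patient_id", "group", "fov_id", "percent_fiber_volume"]].to_csv(fov_path, index=False)
    patients[["patient_id", "group", "mean_volume", "n_fov", "time", "event"]].to_csv(
        patient_path, index=False
    )
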