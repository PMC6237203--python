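"""Synthetic cohort generator: textured "slides", gene-expression matrices
with signature-level group shifts, and exponential survival outcomes tied
to a latent risk.

The generator emulates the statistical structure the pipeline assumes
without any histological realism:

* Gleason pattern 3 is rendered as sparse large ellipses ("single glands"),
  pattern 4 as dense small fused ellipses, on a pink background with
  Gaussian pixel noise — a texture signal that is learnable at 64 px.
* A slide is a single raster composed of one row of tissue patches plus a
  blank background row, so the tissue filter has true negatives to reject.
* Expression is drawn per gene around a random baseline (log2 scale); the
  genes of the informative signatures are mean-shifted upward in the
  Gleason 4+3 group.
* The latent risk is 1.0 x (fraction of pattern-4 patches) +
  1.0 x (mean informative-signature score); survival times are exponential
  with hazard = baseline_hazard * exp(risk_coefficient * latent_risk), with
  uniform administrative censoring calibrated to the requested rate.

The same config + seed reproduces byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io as hio
from . import pathway

#: Gleason-group proportions mimicking the shape of a real prostate cohort
#: (3+3 : 3+4 : 4+3 : 4+4).
GROUP_WEIGHTS = {(3, 3): 43, (3, 4): 146, (4, 3): 101, (4, 4): 49}

DEFAULT_TEXTURES = {
    3: {"n_blobs": (2, 4), "radius_frac": 0.20},
    4: {"n_blobs": (16, 24), "radius_frac": 0.07},
}

_BACKGROUND = np.array([235, 215, 225], dtype=float)   # eosin-pink stroma
_GLAND = np.array([150, 100, 165], dtype=float)        # hematoxylin-purple
_BLANK = 255.0                                         # glass background


@dataclass
class SyntheticCohortConfig:
    n_patients: int = 60
    patches_per_slide: int = 7
    patch_px: int = 64
    n_genes: int = 500
    n_signatures: int = 20
    n_informative_signatures: int = 5
    signature_size: int = 10
    signature_shift: float = 2.0
    gene_noise_sd: float = 1.0
    texture_classes: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_TEXTURES.items()})
    baseline_hazard: float = 0.02     # events / month
    risk_coefficient: float = 1.5     # log-hazard per unit latent risk
    censor_rate: float = 0.3
    risk_weight_image: float = 1.0
    risk_weight_genomic: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_patients", "patches_per_slide", "patch_px",
                     "n_genes", "n_signatures", "signature_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_informative_signatures < 0:
            raise ValueError("n_informative_signatures must be >= 0")
        if self.n_informative_signatures > self.n_signatures:
            raise ValueError(
                "n_informative_signatures exceeds n_signatures")
        if not 0 <= self.censor_rate <= 1:
            raise ValueError("censor_rate must lie in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.n_genes < self.n_signatures * self.signature_size:
            raise ValueError("not enough genes to build disjoint signatures")


@dataclass
class SlideRecord:
    patient_id: str
    image: np.ndarray
    primary: int
    secondary: int
    patch_patterns: list[int]

    @property
    def gleason(self) -> int:
        return self.primary + self.secondary


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    slides: list[SlideRecord]
    expression: pd.DataFrame          # genes x patients, raw scale
    signatures: dict[str, list[str]]
    informative: list[str]
    clinical: pd.DataFrame            # indexed by patient_id
    latent_risk: pd.Series

    @property
    def patient_ids(self) -> list[str]:
        return [s.patient_id for s in self.slides]


def generate_texture_patch(pattern: int, edge_px: int,
                           seed: int | np.random.Generator = 0,
                           texture: dict | None = None) -> np.ndarray:
    """One synthetic tissue patch whose texture encodes the Gleason pattern.

    Pattern 3 draws a few large ellipses, pattern 4 many small ones; both
    add Gaussian pixel noise.  Returns an (edge, edge, 3) uint8 image.
    """
    if pattern not in (3, 4):
        raise ValueError(f"unsupported Gleason pattern {pattern}")
    if edge_px < 16:
        raise ValueError("edge_px must be >= 16")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    tex = texture or DEFAULT_TEXTURES[pattern]
    lo, hi = tex["n_blobs"]
    n_blobs = int(rng.integers(lo, hi + 1))
    radius = tex["radius_frac"] * edge_px

    img = np.tile(_BACKGROUND, (edge_px, edge_px, 1))
    yy, xx = np.mgrid[0:edge_px, 0:edge_px]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, edge_px, size=2)
        ry = radius * rng.uniform(0.7, 1.3)
        rx = radius * rng.uniform(0.7, 1.3)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        mask = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        img[mask] = _GLAND
    img += rng.normal(0, 8.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _allocate_groups(n: int) -> list[tuple[int, int]]:
    """Largest-remainder allocation of patients to Gleason groups."""
    total = sum(GROUP_WEIGHTS.values())
    raw = {g: w * n / total for g, w in GROUP_WEIGHTS.items()}
    counts = {g: int(np.floor(v)) for g, v in raw.items()}
    short = n - sum(counts.values())
    for g in sorted(raw, key=lambda g: raw[g] - counts[g], reverse=True)[:short]:
        counts[g] += 1
    groups = []
    for g, c in counts.items():
        groups.extend([g] * c)
    return groups


def _compose_slide(patches: list[np.ndarray], patch_px: int,
                   rng: np.random.Generator) -> np.ndarray:
    """One row of tissue patches over one blank background row."""
    n = len(patches)
    slide = np.full((2 * patch_px, n * patch_px, 3), _BLANK)
    for k, patch in enumerate(patches):
        slide[:patch_px, k * patch_px:(k + 1) * patch_px] = patch
    slide[patch_px:] += rng.normal(0, 1.0, size=slide[patch_px:].shape)
    return np.clip(slide, 0, 255).astype(np.uint8)


def _censoring_horizon(lam: np.ndarray, target: float) -> float:
    """Administrative horizon tau with E[censored fraction] = target.

    Censoring times are Uniform(0, tau); a subject with hazard lam is
    censored with probability (1 - exp(-lam tau)) / (lam tau).
    """
    def frac(tau):
        return float(np.mean((1 - np.exp(-lam * tau)) / (lam * tau))) - target

    # frac is decreasing in tau, -> 1 as tau -> 0 and -> 0 as tau -> inf
    return brentq(frac, 1e-9, 1e9, xtol=1e-10)


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate slides, expression, signatures and survival for one cohort."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = [f"P{i:04d}" for i in range(n)]
    groups = _allocate_groups(n)
    rng.shuffle(groups)

    # ---- slides ----------------------------------------------------------
    slides = []
    frac4 = np.zeros(n)
    for i, pid in enumerate(pids):
        primary, secondary = groups[i]
        m = config.patches_per_slide
        if primary == secondary:
            patterns = [primary] * m
        else:
            n_secondary = max(1, round(0.3 * m))
            patterns = [primary] * (m - n_secondary) + [secondary] * n_secondary
            rng.shuffle(patterns)
        patches = [generate_texture_patch(
            p, config.patch_px, rng, texture=config.texture_classes[p])
            for p in patterns]
        slides.append(SlideRecord(pid, _compose_slide(
            patches, config.patch_px, rng), primary, secondary, patterns))
        frac4[i] = np.mean([p == 4 for p in patterns])

    # ---- expression + signatures ----------------------------------------
    genes = [f"G{j:05d}" for j in range(config.n_genes)]
    sig_names = [f"SIG_{k:03d}" for k in range(config.n_signatures)]
    signatures = {}
    for k, name in enumerate(sig_names):
        lo = k * config.signature_size
        signatures[name] = genes[lo:lo + config.signature_size]
    informative = sig_names[:config.n_informative_signatures]
    informative_genes = {g for name in informative for g in signatures[name]}

    baseline = rng.uniform(3.0, 8.0, size=config.n_genes)
    L = baseline[:, None] + rng.normal(
        0, config.gene_noise_sd, size=(config.n_genes, n))
    is_43 = np.array([g == (4, 3) for g in groups])
    inf_rows = np.array([g in informative_genes for g in genes])
    L[np.ix_(inf_rows, is_43)] += config.signature_shift
    raw = np.clip(np.exp2(L) - 1.0, 0.0, None)
    expression = pd.DataFrame(raw, index=pd.Index(genes, name="gene"),
                              columns=pids)

    # ---- latent risk -----------------------------------------------------
    if informative:
        prep = pathway.preprocess_expression(expression)
        scored = pathway.score_all(
            prep, {k: signatures[k] for k in informative})
        genomic = scored.scores.mean(axis=0).to_numpy()
    else:
        genomic = np.zeros(n)
    risk = config.risk_weight_image * frac4 \
        + config.risk_weight_genomic * genomic

    # ---- survival + clinical --------------------------------------------
    lam = config.baseline_hazard * np.exp(config.risk_coefficient * risk)
    t_event = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        tau = _censoring_horizon(lam, config.censor_rate)
        c_time = rng.uniform(0, tau, size=n)
        event = (t_event <= c_time).astype(int)
        t_obs = np.minimum(t_event, c_time)
    else:
        event = np.ones(n, dtype=int)
        t_obs = t_event
    t_obs = np.maximum(t_obs, 1e-3)

    clinical = pd.DataFrame({
        "rfs_months": t_obs,
        "event": event,
        "psa": rng.lognormal(2.3, 0.5, size=n),
        "age": np.clip(np.round(rng.normal(62, 8, size=n)), 40, 85),
        "stage": rng.choice([1, 2, 3], size=n, p=[0.3, 0.5, 0.2]),
        "primary_pattern": [g[0] for g in groups],
        "secondary_pattern": [g[1] for g in groups],
    }, index=pd.Index(pids, name="patient_id"))

    return SyntheticCohort(config=config, slides=slides,
                           expression=expression, signatures=signatures,
                           informative=informative, clinical=clinical,
                           latent_risk=pd.Series(risk, index=pids))


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path,
                 slide_format: str = "png") -> Path:
    """Write the cohort in the on-disk formats the pipeline reads."""
    out = Path(out_dir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    for s in cohort.slides:
        hio.write_slide(s.image, out / "slides" / f"{s.patient_id}.{slide_format}")
    hio.write_expression_tsv(cohort.expression, out / "expression.tsv")
    hio.write_gmt(cohort.signatures, out / "signatures.gmt")
    hio.write_clinical_tsv(cohort.clinical, out / "clinical.tsv")
    return out
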