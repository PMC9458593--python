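"""End-to-end pipeline: simulate/quantify -> agreement -> outcome models.

`run_pipeline` chains every stage over a synthetic study (paired sections
plus a clinical cohort), writes machine-readable artefacts (CSV/JSON), a
score-matrix report, and a run manifest capturing inputs, versions, seed
and parameters so a run is exactly reproducible.  Per-biopsy failures are
logged and skipped; the run aborts only on global errors.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import PairAgreement
from .outcome import dgf_analysis
from .quantify import (
    DEFAULT_CUTPOINTS,
    BiopsyPair,
    check_pair_inclusion,
    map_to_remuzzi,
    quantify_pair,
)
from .synthetic import (
    CohortSimConfig,
    SectionSimConfig,
    generate_cohort,
    generate_section_pair,
)

logger = logging.getLogger("sriaquant")

__all__ = ["PipelineConfig", "ScoreMatrix", "build_score_matrix", "run_pipeline",
           "load_config"]


@dataclass(frozen=True)
class ScoreMatrix:
    """K x K cross-tabulation of biopsies by two grading methods."""

    counts: np.ndarray
    method_a: str
    method_b: str

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        K = self.counts.shape[0]
        return pd.DataFrame(
            self.counts,
            index=[f"{self.method_a}={g}" for g in range(K)],
            columns=[f"{self.method_b}={g}" for g in range(K)],
        )

    def plot(self, path: str | Path) -> Path:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        K = self.counts.shape[0]
        ax.imshow(self.counts, cmap="Reds")
        for i in range(K):
            for j in range(K):
                ax.text(j, i, str(self.counts[i, j]), ha="center", va="center")
        ax.set_xlabel(f"IF grade ({self.method_b})")
        ax.set_ylabel(f"IF grade ({self.method_a})")
        ax.set_xticks(range(K))
        ax.set_yticks(range(K))
        fig.tight_layout()
        path = Path(path)
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path


def build_score_matrix(
    grades_a: Sequence[int],
    grades_b: Sequence[int],
    n_categories: int = 4,
    method_a: str = "frozen",
    method_b: str = "paraffin",
) -> ScoreMatrix:
    """Cross-tabulate two equal-length grade vectors (grades 0..K-1)."""
    a = np.asarray(list(grades_a), dtype=int)
    b = np.asarray(list(grades_b), dtype=int)
    if a.size != b.size:
        raise ValueError("grade vectors must have equal length")
    if a.size and (min(a.min(), b.min()) < 0 or max(a.max(), b.max()) >= n_categories):
        raise ValueError(f"grades must lie in 0..{n_categories - 1}")
    counts = np.zeros((n_categories, n_categories), dtype=int)
    np.add.at(counts, (a, b), 1)
    return ScoreMatrix(counts=counts, method_a=method_a, method_b=method_b)


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic run.

    Precedence when loading: CLI flags > config file > these defaults.
    """

    output_dir: str = "sriaquant-run"
    seed: int = 0
    # synthetic study size
    n_pairs: int = 10
    cohort_n: int = 200
    # section simulation
    width_px: int = 1024
    height_px: int = 1024
    microns_per_pixel: float = 2.0
    frozen_delta_pct: float = 7.8
    ice_crystal_density: float = 1.0
    true_fraction_range: tuple[float, float] = (15.0, 50.0)
    # quantification
    channel_method: str = "deconvolution"
    threshold_method: str = "otsu"
    cutpoints_pct: tuple[float, float, float] = DEFAULT_CUTPOINTS
    min_area_mm2: float = 1.0
    # statistics
    alpha: float = 0.05
    screen_alpha: float = 0.1
    # cohort simulation
    or_sria_per_pct: float = 1.1
    or_cit_per_hour: float = 1.089
    target_dgf_prevalence: float = 0.41

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_fraction_range"] = list(self.true_fraction_range)
        d["cutpoints_pct"] = list(self.cutpoints_pct)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("true_fraction_range", "cutpoints_pct"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic study and write all artefacts.

    Stages: simulate pairs -> quantify (pooled per-pair Otsu) -> inclusion
    rule -> Bland–Altman/ICC -> Remuzzi translation -> kappa + score matrix
    -> simulate cohort -> univariate screen + multivariate DGF model.
    Returns the run report (also written as ``report.json``); the manifest
    is fully determined by config + seed.
    """
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    rng = np.random.default_rng(cfg.seed)
    report: dict = {"config": cfg.to_dict()}

    # --- stage 1: simulate + quantify section pairs ---------------------
    lo, hi = cfg.true_fraction_range
    pairs: list[BiopsyPair] = []
    truths: list[tuple[float, float]] = []
    warnings: list[str] = []
    for i in range(cfg.n_pairs):
        seed_i = int(rng.integers(0, 2**31 - 1))
        true_frac = float(rng.uniform(lo, hi))
        sim = SectionSimConfig(
            width_px=cfg.width_px,
            height_px=cfg.height_px,
            microns_per_pixel=cfg.microns_per_pixel,
            true_fraction_pct=true_frac,
            frozen_delta_pct=cfg.frozen_delta_pct,
            ice_crystal_density=cfg.ice_crystal_density,
            seed=seed_i,
        )
        try:
            frozen, paraffin, t_f, t_p = generate_section_pair(sim)
            pair = quantify_pair(
                frozen,
                paraffin,
                channel_method=cfg.channel_method,
                threshold_method=cfg.threshold_method,
            )
            pair = check_pair_inclusion(pair, cfg.min_area_mm2)
            pairs.append(pair)
            truths.append((t_f.realised_fraction_pct, t_p.realised_fraction_pct))
            if not pair.included:
                logger.warning(
                    "pair %s excluded: %s", pair.biopsy_id, pair.exclusion_reason
                )
        except Exception as exc:
            msg = f"pair {i} (seed {seed_i}) failed: {exc}"
            warnings.append(msg)
            logger.warning("%s", msg)
    included = [p for p in pairs if p.included]
    pair_rows = []
    for (p, (tf, tp)) in zip(pairs, truths):
        gf = map_to_remuzzi(p.frozen.fraction_pct, cfg.cutpoints_pct).grade
        gp = map_to_remuzzi(p.paraffin.fraction_pct, cfg.cutpoints_pct).grade
        pair_rows.append(
            {
                "biopsy_id": p.biopsy_id,
                "sria_frozen_pct": p.frozen.fraction_pct,
                "sria_paraffin_pct": p.paraffin.fraction_pct,
                "truth_frozen_pct": tf,
                "truth_paraffin_pct": tp,
                "if_grade_frozen": gf,
                "if_grade_paraffin": gp,
                "area_frozen_mm2": p.frozen.analysed_area_mm2,
                "area_paraffin_mm2": p.paraffin.analysed_area_mm2,
                "included": p.included,
                "exclusion_reason": p.exclusion_reason,
            }
        )
    pair_df = pd.DataFrame(pair_rows)
    pair_df.to_csv(out / "pairs.csv", index=False)
    report["n_pairs_simulated"] = len(pairs)
    report["n_pairs_included"] = len(included)
    report["warnings"] = warnings

    # --- stage 2: agreement statistics ----------------------------------
    inc_df = pair_df[pair_df["included"]] if len(pair_df) else pair_df
    if len(included) >= 3:
        analysis = PairAgreement(
            list(zip(inc_df["sria_frozen_pct"], inc_df["sria_paraffin_pct"])),
            grades_frozen=list(inc_df["if_grade_frozen"]),
            grades_paraffin=list(inc_df["if_grade_paraffin"]),
        )
        ba = analysis.bland_altman()
        icc = analysis.icc(alpha=cfg.alpha)
        kappa = analysis.kappa()
        report["agreement"] = {
            "bland_altman": ba.to_dict(),
            "icc": icc.to_dict(),
            "kappa_translated_grades": kappa.to_dict(),
        }
        flags = analysis.flags()
        flags.insert(0, "biopsy_id", list(inc_df["biopsy_id"]))
        flags.to_csv(out / "pair_flags.csv", index=False)
        matrix = build_score_matrix(
            inc_df["if_grade_frozen"], inc_df["if_grade_paraffin"],
            method_a="SRIA frozen", method_b="SRIA paraffin",
        )
        matrix.to_dataframe().to_csv(out / "score_matrix.csv")
        matrix.plot(out / "score_matrix.png")
        report["score_matrix"] = matrix.counts.tolist()
    else:
        logger.warning(
            "only %d included pairs; agreement statistics skipped (need >= 3)",
            len(included),
        )
        report["agreement"] = None
        report["score_matrix"] = None

    # --- stage 3: cohort + DGF models -----------------------------------
    cohort_cfg = CohortSimConfig(
        n_patients=cfg.cohort_n,
        or_sria_per_pct=cfg.or_sria_per_pct,
        or_cit_per_hour=cfg.or_cit_per_hour,
        target_dgf_prevalence=cfg.target_dgf_prevalence,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    cohort = generate_cohort(cohort_cfg)
    cohort.to_csv(out / "cohort.csv", index=False)
    screen, multi = dgf_analysis(cohort, alpha_in=cfg.screen_alpha)
    uni_rows = []
    for name, f in screen.fits.items():
        t = f.terms[0]
        uni_rows.append(
            {
                "covariate": name,
                "odds_ratio": t.odds_ratio,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "p": t.p,
                "intercept": f.intercept,
                "retained": name in screen.retained,
            }
        )
    uni_df = pd.DataFrame(uni_rows)
    uni_df.to_csv(out / "dgf_univariate.csv", index=False)
    multi.odds_ratios.to_csv(out / "dgf_multivariate.csv")
    report["dgf"] = {
        "prevalence": float(np.asarray(cohort["dgf"]).mean()),
        "univariate": uni_rows,
        "screen_errors": screen.errors,
        "retained": screen.retained,
        "multivariate": multi.to_dict(),
    }

    # --- manifest + report ----------------------------------------------
    manifest = {
        "package": "sriaquant",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "artefacts": sorted(
            p.name for p in out.iterdir() if p.name not in ("run.log", "manifest.json",
                                                            "report.json")
        ),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default)
    )
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    )
    return report


def _setup_logging(logfile: Path) -> None:
    logger.setLevel(logging.INFO)
    have_file = any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == logfile.resolve()
        for h in logger.handlers
    )
    if not have_file:
        logger.addHandler(logging.FileHandler(logfile))
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler())
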