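"""End-to-end orchestration: cohort -> phantoms -> FA/tract strength -> battery.

``run_full`` simulates a cohort, builds one diffusion phantom per subject,
fits tensors and extracts mean FA in thresholded atlas masks (including the
exclusive IFOF-minus-UF mask), runs probabilistic tractography between the
seed and target ROIs, and feeds the assembled table to the correlation
battery.  ``behavior_only`` mode skips the imaging stages and uses the
cohort simulator's analytic surrogates instead.  Everything is
deterministic under the run config's global seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import StudyDesign, subject_summary
from .cohort import (
    EffectConfig,
    draw_traits,
    phantom_params_from_traits,
    simulate_cohort,
    simulate_recall,
)
from .phantom import (
    PhantomLayout,
    SubjectPhantomParams,
    build_phantom,
    make_gradient_table,
    save_dwi,
    save_map,
)
from .stats import default_battery, run_battery
from .tensor import exclusive_mask, fa_map, mean_fa, threshold_mask
from .tractography import (
    TrackingParams,
    count_hits,
    orientation_model_from_tensors,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineStageError", "run_full", "subject_measures", "make_fixtures"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name labels the error."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    effect: EffectConfig = field(default_factory=EffectConfig)
    layout: PhantomLayout = field(default_factory=PhantomLayout)
    tracking: TrackingParams = field(default_factory=lambda: TrackingParams(samples_per_seed_voxel=500))
    mask_threshold: float = 0.10
    q: float = 0.05
    seed: int = 0
    behavior_only: bool = False
    save_volumes: bool = False  # per-subject NIfTI artifacts

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "effect" in raw:
            kwargs["effect"] = EffectConfig(**raw["effect"])
        if "layout" in raw:
            lay = dict(raw["layout"])
            if "grid_shape" in lay:
                lay["grid_shape"] = tuple(lay["grid_shape"])
            kwargs["layout"] = PhantomLayout(**lay)
        if "tracking" in raw:
            kwargs["tracking"] = TrackingParams(**raw["tracking"])
        for k in ("mask_threshold", "q", "seed", "behavior_only", "save_volumes"):
            if k in raw:
                kwargs[k] = raw[k]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        raw = {
            "effect": asdict(self.effect),
            "layout": asdict(self.layout),
            "tracking": asdict(self.tracking),
            "mask_threshold": self.mask_threshold,
            "q": self.q,
            "seed": self.seed,
            "behavior_only": self.behavior_only,
            "save_volumes": self.save_volumes,
        }
        raw["effect"]["trait_corr"] = list(self.effect.trait_corr)
        raw["layout"]["grid_shape"] = list(self.layout.grid_shape)
        for key in ("seed_center", "target_center"):
            raw["layout"][key] = list(raw["layout"][key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(
            {
                "effect": asdict(self.effect),
                "layout": asdict(self.layout),
                "tracking": asdict(self.tracking),
                "mask_threshold": self.mask_threshold,
                "q": self.q,
                "seed": self.seed,
                "behavior_only": self.behavior_only,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def subject_measures(
    layout: PhantomLayout,
    subject_params: SubjectPhantomParams,
    gtab,
    tracking: TrackingParams,
    mask_threshold: float = 0.10,
    rng: Optional[np.random.Generator] = None,
    outdir: Optional[Path] = None,
    subject_id: str = "S000",
) -> dict[str, float]:
    """Imaging measures for one subject: per-tract mean FA (thresholded and
    exclusive masks) and seed-target tract strength with target-ROI size."""
    dwi, _, masks, _ = build_phantom(layout, subject_params, gtab, rng)
    fa, pdirs, _ = fa_map(dwi, return_directions=True)
    uf_bin = threshold_mask(masks["uf"], mask_threshold)
    ifof_bin = threshold_mask(masks["ifof"], mask_threshold)
    ctrl_bin = threshold_mask(masks["control"], mask_threshold)
    ifof_excl = exclusive_mask(ifof_bin, uf_bin)
    model = orientation_model_from_tensors(fa, pdirs)
    ts = count_hits(masks["seed"].prob_map >= 0.5, masks["target"].prob_map >= 0.5,
                    model, tracking)
    if outdir is not None:
        save_dwi(str(outdir / f"{subject_id}_dwi"), dwi)
        save_map(outdir / f"{subject_id}_fa.nii", fa, layout.voxel_size)
    return {
        "uf_fa": mean_fa(fa, uf_bin, "uf", mask_threshold).mean_fa,
        "ifof_fa": mean_fa(fa, ifof_bin, "ifof", mask_threshold).mean_fa,
        "ifof_excl_fa": mean_fa(fa, ifof_excl, "ifof_exclusive", mask_threshold).mean_fa,
        "control_fa": mean_fa(fa, ctrl_bin, "control", mask_threshold).mean_fa,
        "tract_strength": ts.strength,
        "target_size": float(ts.target_roi_size),
    }


def run_full(config: RunConfig, outdir) -> Path:
    """Run the whole pipeline and write cohort table, battery report and
    provenance into ``outdir``.  Returns the output directory path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("vdrdti")
    root.addHandler(handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    try:
        return _run_full(config, outdir)
    finally:
        root.removeHandler(handler)


def _run_full(config: RunConfig, outdir: Path) -> Path:
    design = StudyDesign()
    effect = config.effect
    master = np.random.default_rng(config.seed if config.seed is not None else effect.seed)
    logger.info("run %s: n_subjects=%d behavior_only=%s seed=%d",
                config.digest(), effect.n_subjects, config.behavior_only, config.seed)

    if config.behavior_only:
        try:
            table = simulate_cohort(effect, design, rng=master, surrogates=True)
        except Exception as e:  # pragma: no cover - defensive labeling
            raise PipelineStageError("simulate_cohort", e) from e
        fa_cols = ("uf_fa", "ifof_fa", "control_fa")
    else:
        r_traits, r_recall, r_params, r_imaging = master.spawn(4)
        try:
            traits = draw_traits(effect, r_traits)
            records = simulate_recall(traits, design, effect, r_recall)
            pparams = phantom_params_from_traits(traits, effect, r_params)
        except Exception as e:
            raise PipelineStageError("simulate_cohort", e) from e
        try:
            gtab = make_gradient_table(rng=np.random.default_rng(config.seed))
        except Exception as e:
            raise PipelineStageError("gradient_table", e) from e
        rows = []
        subject_rngs = r_imaging.spawn(effect.n_subjects)
        for i in range(effect.n_subjects):
            sid = f"S{i:03d}"
            s = subject_summary(records[i], design)
            row = {
                "subject_id": sid,
                "mean_high_recall": s.mean_high_recall,
                "mean_low_recall": s.mean_low_recall,
                "mean_selectivity": np.nan if s.mean_selectivity is None else s.mean_selectivity,
            }
            sp = SubjectPhantomParams(
                uf_fa=float(pparams.loc[i, "uf_fa_target"]),
                control_fa=float(pparams.loc[i, "control_fa_target"]),
                ifof_fa=float(pparams.loc[i, "ifof_fa_target"]),
                st_dispersion=float(pparams.loc[i, "st_dispersion"]),
                target_radius=float(pparams.loc[i, "target_radius"]),
            )
            tracking = TrackingParams(
                samples_per_seed_voxel=config.tracking.samples_per_seed_voxel,
                step_size=config.tracking.step_size,
                max_steps=config.tracking.max_steps,
                curvature_threshold=config.tracking.curvature_threshold,
                rng_seed=int(np.random.default_rng([config.seed, i]).integers(2**31)),
            )
            try:
                row.update(
                    subject_measures(
                        config.layout, sp, gtab, tracking, config.mask_threshold,
                        rng=subject_rngs[i],
                        outdir=outdir if config.save_volumes else None,
                        subject_id=sid,
                    )
                )
            except Exception as e:
                raise PipelineStageError(f"imaging[{sid}]", e) from e
            logger.info("subject %s: uf_fa=%.3f strength=%.4f", sid,
                        row["uf_fa"], row["tract_strength"])
            rows.append(row)
        table = pd.DataFrame(rows)
        fa_cols = ("uf_fa", "ifof_fa", "ifof_excl_fa", "control_fa")

    table.to_csv(outdir / "cohort.tsv", sep="\t", index=False, float_format="%.10g")

    try:
        spec = default_battery(fa_columns=fa_cols, q=config.q)
        report = run_battery(table.dropna(subset=["mean_selectivity"]), spec)
    except Exception as e:
        raise PipelineStageError("battery", e) from e
    report.to_tsv(outdir / "battery.tsv")
    report.to_json(outdir / "battery.json")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(
            {
                "config_digest": config.digest(),
                "seed": config.seed,
                "vdrdti_version": __version__,
                "numpy_version": np.__version__,
            },
            fh,
            indent=2,
        )
    config.to_yaml(outdir / "config.yaml")
    logger.info("battery: %d correlations, %d FDR-significant at q=%.2f",
                len(report.correlations), len(report.significant()), report.q)
    return outdir


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_SEED = 7


def make_fixtures(outdir, size: str = "tiny") -> Path:
    """Write small test inputs: the worked-example recall list (four recalled
    words valued 12, 10, 11, 12), a small phantom, and a 3-subject cohort."""
    if size not in ("tiny", "small"):
        raise ValueError("size must be 'tiny' or 'small'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = StudyDesign()

    values = design.list_values()
    recalled = np.zeros(design.words_per_list, bool)
    # one word from each of values 10 and 11, two words valued 12
    recalled[np.flatnonzero(values == 12)[:2]] = True
    recalled[np.flatnonzero(values == 11)[0]] = True
    recalled[np.flatnonzero(values == 10)[0]] = True
    pd.DataFrame(
        {
            "subject_id": "example",
            "list_id": 1,
            "word_idx": np.arange(design.words_per_list),
            "value": values.astype(int),
            "recalled": recalled.astype(int),
        }
    ).to_csv(outdir / "worked_example.tsv", sep="\t", index=False)

    grid = 16 if size == "tiny" else 24
    layout = PhantomLayout(grid_shape=(grid, grid, grid))
    gtab = make_gradient_table(n_dirs=12, rng=np.random.default_rng(FIXTURE_SEED))
    dwi, fa_truth, masks, _ = build_phantom(
        layout, SubjectPhantomParams(), gtab, np.random.default_rng(FIXTURE_SEED)
    )
    save_dwi(str(outdir / "phantom_dwi"), dwi)
    save_map(outdir / "phantom_fa_truth.nii", fa_truth, layout.voxel_size)
    for name, m in masks.items():
        save_map(outdir / f"mask_{name}.nii", m.prob_map, layout.voxel_size)

    # 3-subject table for unit tests (simulate the minimum cohort, keep 3)
    cfg = EffectConfig(n_subjects=4, seed=FIXTURE_SEED)
    simulate_cohort(cfg).head(3).to_csv(outdir / "cohort3.tsv", sep="\t", index=False)
    return outdir
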