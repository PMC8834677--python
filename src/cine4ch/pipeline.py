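"""End-to-end pipeline: simulate, split, train, predict, clean, evaluate.

Stages mirror a study workflow: a phantom cohort is generated (or a real
one loaded), split at the *subject* level into training / validation /
test groups, the U-Net is trained on training frames with validation-based
model selection, test cines are predicted and morphologically cleaned, and
the cleaned masks are scored against ground truth (DSC, Mahalanobis) and
converted to functional parameters and agreement/detection statistics.

Every stage is deterministic for a fixed seed; a failing stage aborts with
its name so partial runs are diagnosable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chambers import CHAMBERS, CHAMBER_CODES
from .cardiac_function import (
    EnlargementCutoffs,
    analyze_labelmaps,
)
from .io import LabelMapSequence, read_cine_pngs, read_labelmap_pngs
from .metrics import dice, mahalanobis
from .phantom import FIELD_OF_VIEW_MM, generate_cohort, simulate_subject
from .postprocess import PostprocessConfig, postprocess_stack
from .preprocess import PreprocessConfig
from .segmentation import TrainedModel, UNetConfig, predict_probs, save_checkpoint, train
from .stats import AgreementReport, agreement_report


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one deterministic end-to-end run needs.

    ``split_fractions`` are subject counts (train, val, test); the default
    desk-scale run uses a 40/10/20 phantom cohort at 64x64 with a depth-2
    U-Net — small enough for a single CPU core while leaving the full-scale
    70/30/50 protocol one config away.
    """

    n_subjects: int = 70
    split_fractions: tuple[int, int, int] = (40, 10, 20)
    raster_size: int = 64
    n_phases: int = 20
    noise_sd: float = 10.0
    enlargement_prevalence: dict[str, float] = field(
        default_factory=lambda: {c: 0.5 for c in CHAMBERS}
    )
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=lambda: PreprocessConfig(target_size=64))
    unet: UNetConfig = field(
        default_factory=lambda: UNetConfig(
            in_size=64, depth=2, base_filters=8, epochs=5,
            learning_rate=0.08, lr_schedule="warmcos",
        )
    )
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    cutoffs: EnlargementCutoffs = field(default_factory=EnlargementCutoffs)
    workdir: str | None = None

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, sub in (
            ("preprocess", PreprocessConfig),
            ("unet", UNetConfig),
            ("postprocess", PostprocessConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        return cls(**raw)

    def to_yaml(self, path: Path | str) -> None:
        raw = dataclasses.asdict(self)
        raw["split_fractions"] = list(self.split_fractions)
        raw.pop("cutoffs", None)
        Path(path).write_text(yaml.safe_dump(raw))


def split_cohort(
    manifest: pd.DataFrame, fractions: tuple[int, int, int], seed: int
) -> pd.DataFrame:
    """Assign each subject to train/val/test, never splitting a subject.

    ``fractions`` are absolute subject counts and must sum to the cohort
    size.  Deterministic for a fixed seed.
    """
    n_train, n_val, n_test = fractions
    if n_train + n_val + n_test != len(manifest):
        raise ValueError(
            f"fractions {fractions} sum to {n_train + n_val + n_test}, "
            f"but the cohort has {len(manifest)} subjects"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(manifest))
    split = np.empty(len(manifest), dtype=object)
    split[perm[:n_train]] = "train"
    split[perm[n_train : n_train + n_val]] = "val"
    split[perm[n_train + n_val :]] = "test"
    out = manifest.copy()
    out["split"] = split
    return out


def _stack_split(
    cines: dict[str, np.ndarray], masks: dict[str, np.ndarray], ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    frames = np.concatenate([cines[sid] for sid in ids], axis=0)
    labs = np.concatenate([masks[sid] for sid in ids], axis=0)
    return frames, labs


def evaluate_masks(
    pred: dict[str, LabelMapSequence], ref: dict[str, LabelMapSequence]
) -> pd.DataFrame:
    """Per subject/phase/chamber DSC and Mahalanobis distance table."""
    rows = []
    for sid, ref_seq in ref.items():
        pred_seq = pred[sid]
        for phase in range(ref_seq.n_phases):
            for ch in CHAMBERS:
                code = CHAMBER_CODES[ch]
                rmask = ref_seq.masks[phase] == code
                pmask = pred_seq.masks[phase] == code
                dsc = dice(rmask, pmask)
                try:
                    md = mahalanobis(rmask, pmask)
                except ValueError:
                    md = float("nan")
                rows.append(
                    {"subject_id": sid, "phase": phase, "chamber": ch, "dsc": dsc, "md": md}
                )
    return pd.DataFrame(rows)


def functional_table(
    labelmaps: dict[str, LabelMapSequence],
    manifest: pd.DataFrame,
    cutoffs: EnlargementCutoffs | None = None,
) -> pd.DataFrame:
    """Per subject/chamber EDA/ESA/FAC + BSA-indexed enlargement calls."""
    meta = manifest.set_index("subject_id")
    rows = []
    for sid, seq in labelmaps.items():
        sex = str(meta.loc[sid, "sex"])
        bsa = float(meta.loc[sid, "bsa_m2"])
        results = analyze_labelmaps(seq, sex=sex, bsa=bsa, cutoffs=cutoffs)
        for ch, res in results.items():
            rows.append(
                {
                    "subject_id": sid,
                    "chamber": ch,
                    "eda_cm2": res.eda,
                    "esa_cm2": res.esa,
                    "esa_phase": res.esa_phase,
                    "fac_pct": res.fac,
                    "eda_indexed": res.eda_indexed,
                    "enlarged": None if res.enlarged is None else int(res.enlarged),
                }
            )
    return pd.DataFrame(rows)


def agreement_table(
    auto: pd.DataFrame, ref: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Per-chamber agreement report (auto vs reference functional values).

    Correlation/Bland-Altman/ICC on EDA, ESA and FAC; ROC of the automated
    BSA-indexed EDA against the ground-truth enlargement flags.
    """
    meta = manifest.set_index("subject_id")
    rows = []
    for ch in CHAMBERS:
        a = auto[auto.chamber == ch].set_index("subject_id").sort_index()
        r = ref[ref.chamber == ch].set_index("subject_id").sort_index()
        ids = a.index.intersection(r.index)
        a, r = a.loc[ids], r.loc[ids]
        truth = meta.loc[ids, f"{ch}_enlarged"].astype(bool).to_numpy()
        for quantity in ("eda_cm2", "esa_cm2", "fac_pct"):
            x = r[quantity].to_numpy(dtype=float)
            y = a[quantity].to_numpy(dtype=float)
            try:
                if quantity == "eda_cm2" and truth.any() and not truth.all():
                    rep = agreement_report(x, y, a["eda_indexed"].to_numpy(dtype=float), truth)
                else:
                    rep = agreement_report(x, y)
            except ValueError as exc:  # cohort too small for a statistic
                warnings.warn(f"{ch}/{quantity}: {exc}")
                rep = AgreementReport(
                    rho=np.nan, rho_p=np.nan, bias=np.nan, loa_low=np.nan,
                    loa_high=np.nan, icc=np.nan, icc_band="undefined",
                )
            rows.append(
                {
                    "chamber": ch,
                    "quantity": quantity,
                    "rho": rep.rho,
                    "rho_p": rep.rho_p,
                    "bias": rep.bias,
                    "loa_low": rep.loa_low,
                    "loa_high": rep.loa_high,
                    "icc": rep.icc,
                    "icc_band": rep.icc_band,
                    "auc": rep.auc,
                    "auc_ci_low": None if rep.auc_ci is None else rep.auc_ci[0],
                    "auc_ci_high": None if rep.auc_ci is None else rep.auc_ci[1],
                    "optimal_cutoff": rep.optimal_cutoff,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Simulate -> split -> train -> predict -> postprocess -> evaluate ->
    analyze -> report.

    Returns a bundle with the manifest, the trained model, the metrics and
    functional tables, and the per-chamber agreement report.  When
    ``config.workdir`` is set, cohort images and all CSV outputs are
    persisted there.
    """
    workdir = Path(config.workdir) if config.workdir else None
    raster = (config.raster_size, config.raster_size)
    pixel_spacing = FIELD_OF_VIEW_MM / config.raster_size
    run_log: list[dict] = []

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                run_log.append(
                    {
                        "stage": name,
                        "seed": config.seed,
                        "elapsed_s": round(time.perf_counter() - self.t0, 3),
                    }
                )
                return False

        return _Ctx()

    def _checksum(df: pd.DataFrame) -> str:
        return hashlib.sha256(
            df.to_csv(index=False).encode()
        ).hexdigest()[:16]

    with _stage("simulate"):
        manifest, all_params = generate_cohort(
            config.n_subjects,
            config.enlargement_prevalence,
            seed=config.seed,
            out_dir=workdir / "cohort" if workdir else None,
            raster_shape=raster,
            noise_sd=config.noise_sd,
            n_phases=config.n_phases,
        )
        cines, gt_masks = {}, {}
        if workdir:
            for sid in manifest.subject_id:
                cines[sid] = read_cine_pngs(workdir / "cohort" / "frames", sid, pixel_spacing).frames
                gt_masks[sid] = read_labelmap_pngs(workdir / "cohort" / "masks", sid, pixel_spacing).masks
        else:
            for i, sid in enumerate(manifest.subject_id):
                cine, labs = simulate_subject(
                    all_params[i], raster, pixel_spacing, seed=config.seed + 7919 * (i + 1)
                )
                cines[sid], gt_masks[sid] = cine.frames, labs.masks

    with _stage("split"):
        manifest = split_cohort(manifest, config.split_fractions, seed=config.seed + 1)
        ids = {s: list(manifest.loc[manifest.split == s, "subject_id"]) for s in ("train", "val", "test")}

    with _stage("train"):
        train_set = _stack_split(cines, gt_masks, ids["train"])
        val_set = _stack_split(cines, gt_masks, ids["val"])
        # one pipeline seed drives every stage, including weight init and
        # batch shuffling
        unet_cfg = dataclasses.replace(config.unet, seed=config.seed + 2)
        trained = train(None, train_set, val_set, unet_cfg)
        if workdir:
            save_checkpoint(trained, workdir / "model.ckpt.npz")

    with _stage("predict"):
        prob_stacks = {
            sid: predict_probs(trained.model, cines[sid]) for sid in ids["test"]
        }

    with _stage("postprocess"):
        pred_masks = {
            sid: postprocess_stack(prob_stacks[sid], config.postprocess, pixel_spacing)
            for sid in ids["test"]
        }

    with _stage("evaluate"):
        ref_masks = {
            sid: LabelMapSequence(masks=gt_masks[sid], pixel_spacing=pixel_spacing)
            for sid in ids["test"]
        }
        metrics_df = evaluate_masks(pred_masks, ref_masks)

    with _stage("analyze"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty-chamber frames are scored, not fatal
            functional_auto = functional_table(pred_masks, manifest, config.cutoffs)
            functional_ref = functional_table(ref_masks, manifest, config.cutoffs)

    with _stage("report"):
        report = agreement_table(functional_auto, functional_ref, manifest)
        if workdir:
            manifest.to_csv(workdir / "manifest.csv", index=False)
            metrics_df.to_csv(workdir / "metrics.csv", index=False)
            functional_auto.to_csv(workdir / "functional_auto.csv", index=False)
            functional_ref.to_csv(workdir / "functional_ref.csv", index=False)
            report.to_csv(workdir / "report.csv", index=False)

    checksums = {
        "manifest": _checksum(manifest),
        "metrics": _checksum(metrics_df),
        "functional_auto": _checksum(functional_auto),
        "functional_ref": _checksum(functional_ref),
        "report": _checksum(report),
    }
    if workdir:
        (workdir / "run_log.json").write_text(
            json.dumps({"stages": run_log, "checksums": checksums}, indent=2)
        )

    return {
        "manifest": manifest,
        "trained": trained,
        "metrics": metrics_df,
        "functional_auto": functional_auto,
        "functional_ref": functional_ref,
        "report": report,
        "pred_masks": pred_masks,
        "ref_masks": ref_masks,
        "run_log": run_log,
        "checksums": checksums,
    }
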