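"""End-to-end orchestration: phantom (optional) -> maps -> alignment ->
summaries -> statistics.

Stages communicate only through declared file artifacts under the output
root; every stage writes a manifest with its parameters and the SHA-256 of
the files it consumed, so a rerun with an identical config is reproducible
and auditable.  Parameters that the underlying publications leave open
(fat spectrum, fat T2, REKINDLE kappa, voxel floor, mask-combine mode,
significance level) are all recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align as al
from . import dixon as dx
from . import dti as dt
from . import metrics as me
from . import stats as st
from . import t2epg as t2m
from .core import LOW_FAT_MUSCLES, read_volume, write_volume, write_summary_table
from .phantom import PhantomSpec, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialisable to/from YAML."""

    out_dir: str = "results"
    phantom: PhantomSpec | None = None
    input_manifest: dict | None = None    # per subject: {"A": dir, "B": dir}
    stages: dict = field(default_factory=lambda: dict(
        dixon=True, t2=True, dti=True, align=True, metrics=True, stats=True))
    fat_t2_ms: float = 150.0
    rekindle_kappa: float = 6.0
    motion_correction: bool = False
    drop_b_below: float | None = None
    denoise_stride: int = 2
    voxel_floor: int = al.DEFAULT_VOXEL_FLOOR
    combine: str = "intersection"
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        phantom = raw.pop("phantom", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if phantom is not None:
            cfg.phantom = PhantomSpec(**phantom)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out: Path, stage: str, params: dict, inputs: list):
    man = {
        "stage": stage,
        "parameters": params,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
    }
    mdir = out / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    (mdir / f"{stage}.json").write_text(json.dumps(man, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a dict of result paths.

    Stage order: phantom (if configured) -> dixon -> t2 -> dti -> align ->
    metrics -> stats.  ``metrics`` refuses to run without the matched masks
    that ``align`` produces; a stage failure aborts the run with that
    stage's diagnostics while earlier results stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = {"out_dir": str(out)}

    if config.phantom is not None:
        data_dir = out / "data"
        generate_dataset(config.phantom, data_dir)
        subjects = {f"sub-{s:02d}": {t: data_dir / f"sub-{s:02d}" / f"ses-{t}" for t in ("A", "B")}
                    for s in range(config.phantom.n_subjects)}
        clinical = pd.concat(
            [pd.read_csv(data_dir / sub / "clinical.csv").assign(subject=sub)
             for sub in subjects], ignore_index=True)
        _write_manifest(out, "phantom", dataclasses.asdict(config.phantom), [])
    elif config.input_manifest is not None:
        subjects = {sub: {t: Path(p) for t, p in sess.items()}
                    for sub, sess in config.input_manifest.items()}
        clin_paths = [Path(p).parent / "clinical.csv" for sess in config.input_manifest.values()
                      for p in list(sess.values())[:1]]
        frames = [pd.read_csv(p) for p in clin_paths if p.exists()]
        clinical = pd.concat(frames, ignore_index=True) if frames else None
    else:
        raise PipelineError("config needs either a phantom spec or an input manifest")

    all_records = []
    for sub, sessions in subjects.items():
        maps_by_session = {}
        labels = {}
        water = {}
        for t, ses_dir in sessions.items():
            ses_out = out / "derived" / sub / f"ses-{t}"
            labels[t] = read_volume(ses_dir / "labels.nii.gz", "labels")
            maps = {}
            if config.stages.get("dixon", True):
                series = read_volume(ses_dir / "dixon.nii.gz", "complex_echoes")
                fit = dx.ideal_fit(series)
                ff = dx.fat_fraction(fit)
                maps["ff"] = ff
                water[t] = fit.water
                for name, vol in (("ff", ff), ("b0", fit.psi), ("r2star", fit.r2star),
                                  ("water", fit.water)):
                    write_volume(vol, ses_out / f"{name}.nii.gz")
            if config.stages.get("t2", True):
                train = read_volume(ses_dir / "t2_train.nii.gz", "echo_train")
                efit = t2m.fit_t2(train, t2f_fixed=config.fat_t2_ms)
                maps["t2"] = efit.t2w
                write_volume(efit.t2w, ses_out / "t2map.nii.gz")
            if config.stages.get("dti", True):
                dwi = read_volume(ses_dir / "dwi.nii.gz", "dwi")
                den, noise = dt.mp_denoise(dwi, stride=config.denoise_stride)
                if config.motion_correction:
                    den, _ = dt.correct_motion_eddy(den)
                tens = dt.fit_tensor_iwlls_rekindle(
                    den, noise, kappa=config.rekindle_kappa,
                    drop_b_below=config.drop_b_below)
                md, fa = dt.tensor_metrics(tens)
                maps["md"], maps["fa"], maps["snr"] = md, fa, noise.snr
                for name, vol in (("md", md), ("fa", fa), ("snr", noise.snr)):
                    write_volume(vol, ses_out / f"{name}.nii.gz")
            maps_by_session[t] = maps

        if config.stages.get("align", True):
            if "A" not in water:
                raise PipelineError("alignment requires the Dixon stage (water images)")
            T = al.register_sessions(water["A"], water["B"])
            matched = al.propagate_and_match(
                labels["A"], labels["B"], T,
                combine=config.combine, voxel_floor=config.voxel_floor)
            qc = al.alignment_qc(matched, labels["B"])
            mdir = out / "matched" / sub
            write_volume(matched.maskA_matched, mdir / "maskA_matched.nii.gz")
            write_volume(matched.maskB_matched, mdir / "maskB_matched.nii.gz")
            qc.to_csv(mdir / "alignment_qc.csv", index=False)
            matched_masks = {"A": matched.maskA_matched, "B": matched.maskB_matched}
        else:
            matched_masks = None

        if config.stages.get("metrics", True):
            if matched_masks is None:
                raise PipelineError(
                    "metrics requires matched masks: enable the align stage")
            for t in ("A", "B"):
                recs = me.summarize_session(
                    maps_by_session[t], matched_masks[t], subject=sub, time_point=t)
                all_records.extend(recs)

    if config.stages.get("metrics", True):
        summary = write_summary_table(all_records, out / "summary.csv")
        results["summary"] = str(out / "summary.csv")
        _write_manifest(out, "metrics", dict(voxel_floor=config.voxel_floor), [out / "summary.csv"])

        if config.stages.get("stats", True):
            stats_dir = out / "stats"
            stats_dir.mkdir(parents=True, exist_ok=True)
            rows = []
            long = summary.melt(
                id_vars=["subject", "time_point", "muscle", "side", "SNR"],
                value_vars=["FF", "CSA", "cCSA", "T2", "MD", "FA"],
                var_name="outcome", value_name="value").dropna(subset=["value"])
            for outcome in ("FF", "CSA", "cCSA", "T2", "MD", "FA"):
                sel = long[long.outcome == outcome]
                if sel.empty or sel.time_point.nunique() < 2:
                    continue
                spec = st.LMMSpec(outcome=outcome, include_snr=outcome in ("MD", "FA"),
                                  alpha=config.alpha)
                try:
                    rows.append(dict(block="all", **st.fit_lmm(sel, spec).summary_row()))
                    rows.append(dict(block="without_low_fat", **st.subset_analysis(
                        sel, spec, exclude=LOW_FAT_MUSCLES).summary_row()))
                    rows.append(dict(block="low_fat_only", **st.subset_analysis(
                        sel, spec, restrict_to=LOW_FAT_MUSCLES).summary_row()))
                except Exception as err:  # singular subsets keep the run alive
                    rows.append(dict(block="all", outcome=outcome, error=str(err)))
            lmm_table = pd.DataFrame(rows)
            lmm_table.to_csv(stats_dir / "qmri_lmm.csv", index=False)
            results["qmri_lmm"] = str(stats_dir / "qmri_lmm.csv")
            if clinical is not None:
                tests = st.paired_tests(clinical)
                tests.to_csv(stats_dir / "clinical_paired_tests.csv", index=False)
                results["clinical_tests"] = str(stats_dir / "clinical_paired_tests.csv")
            _write_manifest(out, "stats", dict(alpha=config.alpha), [out / "summary.csv"])

    return results
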