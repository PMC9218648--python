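"""End-to-end pipeline: simulate -> preprocess -> dtf/slope/cfd -> stats -> classify.

Each stage reads its inputs from the output directory, writes its products
under ``<out>/<stage>/`` and records a manifest entry (config hash + output
paths).  A stage is skipped when its manifest entry matches the current
configuration and all outputs exist, unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import cfd as cfd_mod
from . import classify as clf
from . import core_io, spectral, stats, synthetic
from . import dtf as dtf_mod

logger = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "dtf", "slope", "cfd", "stats", "classify-soz", "predict-outcome"]


class CohortConfig(BaseModel):
    n_patients: int = 27
    electrodes_per_patient: int = 24
    soz_fraction: float = 116 / 689
    base: float = synthetic.DEFAULT_BASE_COUPLING
    delta_free: float = synthetic.DEFAULT_DELTA_FREE
    delta_nonfree: float = synthetic.DEFAULT_DELTA_NONFREE
    outcome_free: int = 19
    outcome_nonfree: int = 8
    duration: float = 600.0
    fs: float = 500.0
    n_cfc: int = 1
    reverse: bool = False


class PreprocessConfig(BaseModel):
    analysis_fs: float = 500.0
    line_freq: float = 60.0
    harmonics: int = 1
    artifact_z: float = 6.0
    segment_length: float = 180.0
    total_length: float | None = None  # None: use the whole recording
    epoch_length: float = 1.0


class DtfConfig(BaseModel):
    order: int | None = 6  # None: AIC/BIC selection up to p_max
    p_max: int = 12
    criterion: str = "aic"
    fmax: int = 250


class SlopeConfig(BaseModel):
    max_peaks: int = 6
    peak_threshold: float = 2.0


class CfdConfig(BaseModel):
    enabled: bool = False  # expensive; off unless requested
    max_pairs: int = 10
    phase_freqs: list[float] = Field(default_factory=lambda: [2.0, 3.0, 4.0])
    amp_freqs: list[float] = Field(default_factory=lambda: [80.0, 100.0, 120.0])
    k: int = 3
    n_init: int = 20


class ClassifyConfig(BaseModel):
    folds: int = 5
    n_trees: int = 500
    k_neighbors: int = 5
    grouped: bool = False


class PipelineConfig(BaseModel):
    out_dir: str
    seed: int = 0
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    dtf: DtfConfig = Field(default_factory=DtfConfig)
    slope: SlopeConfig = Field(default_factory=SlopeConfig)
    cfd: CfdConfig = Field(default_factory=CfdConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {}
        )

    # -- manifest bookkeeping -------------------------------------------------
    def _stage_hash(self, stage: str) -> str:
        section = {
            "simulate": self.cfg.cohort,
            "preprocess": self.cfg.preprocess,
            "dtf": self.cfg.dtf,
            "slope": self.cfg.slope,
            "cfd": self.cfg.cfd,
            "stats": None,
            "classify-soz": self.cfg.classify,
            "predict-outcome": self.cfg.classify,
        }[stage]
        payload = {
            "seed": self.cfg.seed,
            "section": section.model_dump() if section is not None else {},
        }
        return _hash(payload)

    def _up_to_date(self, stage: str) -> bool:
        entry = self.manifest.get(stage)
        if not entry or entry.get("config_hash") != self._stage_hash(stage):
            return False
        return all((self.out / p).exists() for p in entry.get("outputs", []))

    def _record(self, stage: str, outputs: list[Path], t0: float) -> None:
        self.manifest[stage] = {
            "config_hash": self._stage_hash(stage),
            "outputs": [str(p.relative_to(self.out)) for p in outputs],
            "seconds": round(time.time() - t0, 2),
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))

    # -- stage implementations ------------------------------------------------
    def simulate(self) -> None:
        c = self.cfg.cohort
        cohort_dir = self.out / "cohort"
        synthetic.simulate_cohort(
            cohort_dir,
            n_patients=c.n_patients,
            electrodes_per_patient=c.electrodes_per_patient,
            soz_fraction=c.soz_fraction,
            base=c.base,
            delta_free=c.delta_free,
            delta_nonfree=c.delta_nonfree,
            outcome_mix=(c.outcome_free, c.outcome_nonfree),
            duration=c.duration,
            fs=c.fs,
            seed=self.cfg.seed,
            n_cfc=c.n_cfc,
            reverse=c.reverse,
        )
        self._record("simulate", [cohort_dir / "manifest.json"], time.time())

    def _manifest_cohort(self) -> core_io.CohortManifest:
        path = self.out / "cohort" / "manifest.json"
        if not path.exists():
            raise FileNotFoundError("cohort manifest missing; run the simulate stage first")
        return core_io.CohortManifest.load(path)

    def preprocess(self) -> None:
        t0 = time.time()
        p = self.cfg.preprocess
        cohort_dir = self.out / "cohort"
        stage_dir = self.out / "preprocess"
        stage_dir.mkdir(exist_ok=True)
        manifest = self._manifest_cohort()
        outputs = []
        for pat in manifest.patients:
            rec = core_io.read_recording(
                cohort_dir / pat.recording_paths[0],
                cohort_dir / pat.channel_table,
                expected_fs=pat.fs,
            )
            rec = core_io.exclude_white_matter(rec)
            rec = core_io.notch_filter(rec, p.line_freq, p.harmonics)
            rec = core_io.resample_recording(rec, p.analysis_fs)
            if p.total_length is not None:
                rec = core_io.select_interictal_segments(
                    rec, p.segment_length, p.total_length, p.artifact_z
                )
            ep = core_io.epoch(rec, p.epoch_length)
            out_path = stage_dir / f"{pat.id}_epochs.npz"
            np.savez(
                out_path,
                data=ep.data.astype(np.float32),
                fs=ep.fs,
                epoch_length=ep.epoch_length,
                labels=np.array(rec.labels),
                soz=rec.soz_mask,
                pos=np.array([c.position for c in rec.channels]),
            )
            outputs.append(out_path)
        self._record("preprocess", outputs, t0)

    def _load_epochs(self, pid: str) -> tuple[core_io.EpochedData, np.ndarray, np.ndarray]:
        path = self.out / "preprocess" / f"{pid}_epochs.npz"
        if not path.exists():
            raise FileNotFoundError(f"missing preprocess output for {pid}; run the preprocess stage")
        z = np.load(path, allow_pickle=False)
        channels = [
            core_io.ChannelInfo(label=str(l), position=tuple(p), soz=bool(s))
            for l, p, s in zip(z["labels"], z["pos"], z["soz"])
        ]
        ep = core_io.EpochedData(
            data=z["data"].astype(float),
            fs=float(z["fs"]),
            epoch_length=float(z["epoch_length"]),
            channels=channels,
        )
        return ep, z["soz"], z["pos"]

    def dtf(self) -> None:
        t0 = time.time()
        d = self.cfg.dtf
        stage_dir = self.out / "dtf"
        stage_dir.mkdir(exist_ok=True)
        manifest = self._manifest_cohort()
        outputs = []
        flows = {}
        freqs = np.arange(1.0, d.fmax + 1.0)
        for pat in manifest.patients:
            ep, soz, _ = self._load_epochs(pat.id)
            order = d.order or dtf_mod.select_order(ep, d.p_max, d.criterion)
            model = dtf_mod.fit_mvar(ep, order)
            tensor = dtf_mod.dtf(model, freqs, labels=[c.label for c in ep.channels])
            h5_path = stage_dir / f"{pat.id}_dtf.h5"
            dtf_mod.save_dtf(h5_path, tensor)
            fl = dtf_mod.flow_between_groups(tensor, soz)
            flows[pat.id] = fl
            outputs.append(h5_path)
        rows = []
        for pid, fl in flows.items():
            rows.append(
                {"patient": pid, "direction": "non_to_soz", **{f"f{int(f)}": v for f, v in zip(fl.freqs, fl.non_to_soz)}}
            )
            rows.append(
                {"patient": pid, "direction": "soz_to_non", **{f"f{int(f)}": v for f, v in zip(fl.freqs, fl.soz_to_non)}}
            )
        flow_path = stage_dir / "flow_summary.tsv"
        pd.DataFrame(rows).to_csv(flow_path, sep="\t", index=False)
        outputs.append(flow_path)
        self._record("dtf", outputs, t0)

    def slope(self) -> None:
        t0 = time.time()
        s = self.cfg.slope
        stage_dir = self.out / "slope"
        stage_dir.mkdir(exist_ok=True)
        manifest = self._manifest_cohort()
        settings = spectral.FitSettings(max_peaks=s.max_peaks, peak_threshold=s.peak_threshold)
        tables = []
        for pat in manifest.patients:
            ep, _, _ = self._load_epochs(pat.id)
            fmax = min(250.0, ep.fs / 2)
            ps = spectral.compute_psd(ep, np.arange(1.0, fmax + 1.0))
            fits = spectral.fit_aperiodic(ps, settings)
            tables.append(spectral.slope_table(fits, ep.channels, patient=pat.id))
        table = pd.concat(tables, ignore_index=True)
        path = stage_dir / "slopes.tsv"
        table.to_csv(path, sep="\t", index=False)
        self._record("slope", [path], t0)

    def cfd(self) -> None:
        t0 = time.time()
        c = self.cfg.cfd
        stage_dir = self.out / "cfd"
        stage_dir.mkdir(exist_ok=True)
        if not c.enabled:
            path = stage_dir / "skipped.json"
            path.write_text(json.dumps({"enabled": False}))
            self._record("cfd", [path], t0)
            return
        manifest = self._manifest_cohort()
        rng = np.random.default_rng(self.cfg.seed)
        outputs = []
        dominants = {"soz_phase": [], "non_phase": []}
        for pat in manifest.patients:
            ep, soz, _ = self._load_epochs(pat.id)
            sig = ep.data.transpose(1, 0, 2).reshape(ep.n_channels, -1)
            soz_idx = np.where(soz)[0]
            non_idx = np.where(~soz)[0]
            for key, (src_pool, dst_pool) in {
                "soz_phase": (soz_idx, non_idx),
                "non_phase": (non_idx, soz_idx),
            }.items():
                maps = []
                for _ in range(min(c.max_pairs, src_pool.size * dst_pool.size)):
                    i = int(rng.choice(src_pool))
                    j = int(rng.choice(dst_pool))
                    maps.append(
                        cfd_mod.cfd_map(
                            sig[i],
                            sig[j],
                            ep.fs,
                            phase_freqs=np.array(c.phase_freqs),
                            amp_freqs=np.array(c.amp_freqs),
                            pair=(ep.channels[i].label, ep.channels[j].label),
                        )
                    )
                if len(maps) >= c.k:
                    pattern = cfd_mod.kmeans_consistent_pattern(
                        maps, k=c.k, seed=self.cfg.seed, n_init=c.n_init
                    )
                    dominants[key].append(pattern.dominant_map)
            h5 = stage_dir / f"{pat.id}_cfd.h5"
            cfd_mod.save_cfd_maps(h5, maps)
            outputs.append(h5)
        summary = {
            key: np.mean(doms, axis=0).tolist() if doms else None
            for key, doms in dominants.items()
        }
        path = stage_dir / "dominant_patterns.json"
        path.write_text(json.dumps(summary))
        outputs.append(path)
        self._record("cfd", outputs, t0)

    def stats(self) -> None:
        t0 = time.time()
        stage_dir = self.out / "stats"
        stage_dir.mkdir(exist_ok=True)
        flow_path = self.out / "dtf" / "flow_summary.tsv"
        if not flow_path.exists():
            raise FileNotFoundError("flow summary missing; run the dtf stage first")
        flows = pd.read_csv(flow_path, sep="\t")
        manifest = self._manifest_cohort()
        free_ids = {p.id for p in manifest.patients if p.seizure_free}
        fcols = [c for c in flows.columns if c.startswith("f")]

        n2s = flows[flows.direction == "non_to_soz"].set_index("patient")[fcols]
        s2n = flows[flows.direction == "soz_to_non"].set_index("patient")[fcols]
        fig2 = stats.per_frequency_test(n2s.to_numpy(), s2n.to_numpy(), alpha=0.01)

        deltas = (n2s.mean(axis=1) - s2n.mean(axis=1)).rename("delta")
        free_mask = deltas.index.isin(free_ids)
        from scipy import stats as sstats

        if free_mask.any() and (~free_mask).any() and free_mask.sum() > 1 and (~free_mask).sum() > 1:
            t_out, p_out = sstats.ttest_ind(
                deltas[free_mask], deltas[~free_mask], equal_var=False
            )
        else:
            t_out, p_out = float("nan"), float("nan")

        slope_path = self.out / "slope" / "slopes.tsv"
        fig4 = None
        if slope_path.exists():
            fig4 = stats.slope_group_test(pd.read_csv(slope_path, sep="\t"))

        summary = {
            "fig2_flow": {
                "n_significant_bins": int(fig2.rejected.sum()),
                "mean_non_to_soz": float(n2s.to_numpy().mean()),
                "mean_soz_to_non": float(s2n.to_numpy().mean()),
            },
            "fig4_slope": fig4,
            "fig5_outcome": {
                "t": float(t_out),
                "p": float(p_out),
                "mean_delta_free": float(deltas[free_mask].mean()) if free_mask.any() else None,
                "mean_delta_nonfree": float(deltas[~free_mask].mean()) if (~free_mask).any() else None,
            },
        }
        path = stage_dir / "summary.json"
        path.write_text(json.dumps(summary, indent=1, sort_keys=True))
        deltas.to_csv(stage_dir / "asymmetry.tsv", sep="\t")
        self._record("stats", [path, stage_dir / "asymmetry.tsv"], t0)

    def _load_tensors(self):
        manifest = self._manifest_cohort()
        tensors, masks, outcomes = {}, {}, {}
        for pat in manifest.patients:
            path = self.out / "dtf" / f"{pat.id}_dtf.h5"
            if not path.exists():
                raise FileNotFoundError(f"DTF tensor missing for {pat.id}; run the dtf stage")
            tensors[pat.id] = dtf_mod.load_dtf(path)
            _, soz, _ = self._load_epochs(pat.id)
            masks[pat.id] = soz
            outcomes[pat.id] = pat.seizure_free
        return tensors, masks, outcomes

    def classify_soz(self) -> None:
        t0 = time.time()
        stage_dir = self.out / "classify_soz"
        stage_dir.mkdir(exist_ok=True)
        tensors, masks, _ = self._load_tensors()
        rows_X, rows_y, rows_id = [], [], []
        for pid, tensor in tensors.items():
            ft = clf.electrode_features(tensor, patient=pid)
            rows_X.append(ft.X)
            rows_y.append(masks[pid].astype(int))
            rows_id += [pid] * ft.n
        table = clf.FeatureTable(
            X=np.concatenate(rows_X), y=np.concatenate(rows_y), ids=rows_id, level="electrode"
        )
        report = clf.crossvalidate(
            table,
            folds=self.cfg.classify.folds,
            seed=self.cfg.seed,
            k_neighbors=self.cfg.classify.k_neighbors,
            n_trees=self.cfg.classify.n_trees,
            grouped=self.cfg.classify.grouped,
        )
        path = stage_dir / "report.json"
        report.to_json(path)
        pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
            stage_dir / "roc.tsv", sep="\t", index=False
        )
        self._record("classify-soz", [path, stage_dir / "roc.tsv"], t0)

    def predict_outcome(self) -> None:
        t0 = time.time()
        stage_dir = self.out / "predict_outcome"
        stage_dir.mkdir(exist_ok=True)
        tensors, masks, outcomes = self._load_tensors()
        outputs = []
        for source in ("clinical", "model"):
            report = clf.two_stage_outcome(
                tensors,
                masks,
                outcomes,
                soz_source=source,
                folds=self.cfg.classify.folds,
                seed=self.cfg.seed,
                n_trees=self.cfg.classify.n_trees,
            )
            path = stage_dir / f"report_{source}.json"
            report.to_json(path)
            outputs.append(path)
        self._record("predict-outcome", outputs, t0)

    # -- driver ---------------------------------------------------------------
    def run(self, stages: list[str] | None = None, force: bool = False) -> dict:
        stages = stages or STAGES
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        ran, skipped = [], []
        methods = {
            "simulate": self.simulate,
            "preprocess": self.preprocess,
            "dtf": self.dtf,
            "slope": self.slope,
            "cfd": self.cfd,
            "stats": self.stats,
            "classify-soz": self.classify_soz,
            "predict-outcome": self.predict_outcome,
        }
        for stage in STAGES:
            if stage not in stages:
                continue
            if not force and self._up_to_date(stage):
                logger.info("stage %s up to date; skipped", stage)
                skipped.append(stage)
                continue
            logger.info("running stage %s", stage)
            methods[stage]()
            ran.append(stage)
        return {"ran": ran, "skipped": skipped}


def run(config: PipelineConfig, stages: list[str] | None = None, force: bool = False) -> dict:
    return Pipeline(config).run(stages, force)
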