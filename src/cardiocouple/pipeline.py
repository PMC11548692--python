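"""End-to-end orchestration: synth -> preprocess -> couple -> mrp -> encode ->
classify (autoencoder compression + SVM-RFE) -> featurestats.

Each stage writes its artifact plus a JSON manifest recording the parameters,
the upstream manifest hashes, and the SHA-256 of its outputs. A rerun with
unchanged inputs skips completed stages; a corrupted or removed intermediate
triggers recomputation of exactly the downstream stages.

Two scale profiles exist. ``full`` mirrors the clinical-scale method (5-min
records, full-width CNN, 2000-d codes, 400-d latents, 1000 autoencoder epochs).
``desk`` is the proportionally scaled profile used for tests and the synthetic
benchmark: 30-s records, width_divisor 8, target_len 500, 250-d codes, 50-d
latents, 200 autoencoder epochs — the same pipeline, an eighth the width.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import deep_encoder as de
from . import stats as fstats
from .autoencoder import AEConfig, encode as ae_encode, train_autoencoder
from .coupling import CouplingSolveConfig, couple_segment
from .io_preprocess import read_manifest, preprocess_record, write_segments, read_segments
from .mrp import EmbeddingConfig, render_mrp
from .select_classify import CVReport, GridSpec, rfe_rank, run_cv
from .synthetic import SynthConfig, synth_dataset, write_dataset

logger = logging.getLogger(__name__)

MODALITIES = de.MODALITIES


@dataclass
class PipelineConfig:
    run_dir: str = "run"
    seed: int = 0
    profile: str = "desk"  # 'desk' | 'full'
    # synthesis (omitted when an external manifest is supplied)
    synth: SynthConfig | None = None
    manifest: str | None = None
    # preprocessing
    window_s: float = 10.0
    overlap_frac: float = 0.0
    notch_hz: float = 50.0
    # coupling
    reg_lambda: float = 1e-3
    # imaging
    target_len: int = 1000
    decimate: str = "subsample"
    # encoder
    width_divisor: int = 1
    projection_dim: int = 2000
    encoder_mode: str = "random"  # 'random' | 'trained' | 'pretrained'
    encoder_epochs: int = 30
    checkpoint: str | None = None
    # autoencoder
    ae_widths: tuple = (2000, 1000, 400, 1000, 2000)
    ae_epochs: int = 1000
    # classification
    cv_folds: int = 5
    rfe_step: int = 1

    def __post_init__(self) -> None:
        if self.profile == "desk":
            self.width_divisor = max(self.width_divisor, 8)
            self.target_len = min(self.target_len, 500)
            self.ae_epochs = min(self.ae_epochs, 200)
            d = self.width_divisor
            self.projection_dim = min(self.projection_dim, 2000 // d)
            self.ae_widths = (
                2000 // d,
                1000 // d,
                400 // d,
                1000 // d,
                2000 // d,
            )
            if self.synth is not None and self.synth.duration_s > 30:
                self.synth = dataclasses.replace(self.synth, duration_s=30.0)
        if self.ae_widths[0] != self.projection_dim:
            raise ValueError("autoencoder input width must equal projection_dim")
        if self.encoder_mode not in ("random", "trained", "pretrained"):
            raise ValueError("encoder_mode must be random|trained|pretrained")

    @property
    def latent_dim(self) -> int:
        return self.ae_widths[len(self.ae_widths) // 2]

    def branch_spec(self) -> de.BranchSpec:
        return de.BranchSpec(
            projection_dim=self.projection_dim, width_divisor=self.width_divisor
        )

    @classmethod
    def desk(cls, seed: int = 0, n_per_class: int = 20, **kw) -> "PipelineConfig":
        synth = kw.pop("synth", None) or SynthConfig(
            n_per_class=n_per_class, duration_s=30.0, seed=seed
        )
        return cls(profile="desk", seed=seed, synth=synth, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synth", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "synth"})
        if synth is not None:
            cfg.synth = SynthConfig(**synth)
        return cfg


# ---------------------------------------------------------------------------
# stage bookkeeping


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()


class _Stages:
    """Manifest-driven stage runner with content-hash caching."""

    def __init__(self, run_dir: Path):
        self.run_dir = run_dir
        self.dir = run_dir / "manifests"
        self.dir.mkdir(parents=True, exist_ok=True)

    def _manifest_path(self, name: str) -> Path:
        return self.dir / f"{name}.json"

    def manifest_hash(self, name: str) -> str | None:
        p = self._manifest_path(name)
        return _sha256(p) if p.exists() else None

    def is_valid(self, name: str, params: dict, upstream: list[str]) -> bool:
        p = self._manifest_path(name)
        if not p.exists():
            return False
        m = json.loads(p.read_text())
        if m.get("params_hash") != _params_hash(params):
            return False
        for up in upstream:
            if m.get("inputs", {}).get(up) != self.manifest_hash(up):
                return False
        for rel, digest in m.get("outputs", {}).items():
            f = self.run_dir / rel
            if not f.exists() or _sha256(f) != digest:
                return False
        return True

    def record(self, name: str, params: dict, upstream: list[str], outputs: list[Path]) -> None:
        m = {
            "stage": name,
            "params": params,
            "params_hash": _params_hash(params),
            "inputs": {up: self.manifest_hash(up) for up in upstream},
            "outputs": {
                str(p.relative_to(self.run_dir)): _sha256(p) for p in outputs
            },
            "time": time.time(),
        }
        self._manifest_path(name).write_text(json.dumps(m, indent=2, default=str))

    def run(self, name: str, params: dict, upstream: list[str], fn) -> bool:
        """Execute fn() unless the cached stage is still valid; returns True if run."""
        if self.is_valid(name, params, upstream):
            logger.info("stage %s: cached, skipping", name)
            return False
        t0 = time.time()
        logger.info("stage %s: running (params=%s)", name, params)
        outputs = fn()
        self.record(name, params, upstream, outputs)
        logger.info("stage %s: done in %.1fs", name, time.time() - t0)
        return True


# ---------------------------------------------------------------------------
# stage implementations


def stage_synth(cfg: PipelineConfig, st: _Stages) -> Path:
    raw = st.run_dir / "raw"
    if cfg.manifest is not None:
        return Path(cfg.manifest)
    params = dataclasses.asdict(cfg.synth)

    def fn():
        manifest = write_dataset(synth_dataset(cfg.synth), raw)
        return sorted(raw.glob("*.csv"))

    st.run("synth", params, [], fn)
    return raw / "manifest.csv"


def stage_preprocess(cfg: PipelineConfig, st: _Stages, manifest: Path) -> Path:
    out = st.run_dir / "segments.h5"
    params = {
        "manifest": str(manifest),
        "window_s": cfg.window_s,
        "overlap_frac": cfg.overlap_frac,
        "notch_hz": cfg.notch_hz,
    }

    def fn():
        fs = cfg.synth.fs if cfg.synth else 1000.0
        records = read_manifest(manifest, fs=fs)
        segs = []
        for rec in records:
            segs.extend(
                preprocess_record(rec, cfg.window_s, cfg.overlap_frac, cfg.notch_hz)
            )
        if not segs:
            raise RuntimeError("stage preprocess produced no segments")
        write_segments(out, segs, fs)
        return [out]

    st.run("preprocess", params, ["synth"] if cfg.manifest is None else [], fn)
    return out


def stage_couple(cfg: PipelineConfig, st: _Stages) -> Path:
    seg_path = st.run_dir / "segments.h5"
    out = st.run_dir / "segments_coupled.h5"
    params = {"reg_lambda": cfg.reg_lambda}

    def fn():
        segs, fs = read_segments(seg_path)
        ccfg = CouplingSolveConfig(reg_lambda=cfg.reg_lambda)
        coupled = [couple_segment(s, ccfg) for s in segs]
        write_segments(out, coupled, fs)
        return [out]

    st.run("couple", params, ["preprocess"], fn)
    return out


def stage_mrp(cfg: PipelineConfig, st: _Stages) -> Path:
    seg_path = st.run_dir / "segments_coupled.h5"
    out = st.run_dir / "images.h5"
    params = {"target_len": cfg.target_len, "decimate": cfg.decimate}

    def fn():
        segs, _ = read_segments(seg_path)
        ecfg = EmbeddingConfig(target_len=cfg.target_len, decimate=cfg.decimate)
        with h5py.File(out, "w") as f:
            n = len(segs)
            dsets = {
                m: f.create_dataset(
                    m, shape=(n, 224, 224, 3), dtype="float16"
                )
                for m in MODALITIES
            }
            f.create_dataset(
                "seg_id", data=np.array([s.seg_id for s in segs], dtype="S")
            )
            f.create_dataset(
                "subject_id", data=np.array([s.subject_id for s in segs], dtype="S")
            )
            f.create_dataset("label", data=np.array([s.label for s in segs]))
            for i, s in enumerate(segs):
                channels = {
                    "ecg": s.ecg_seg,
                    "pcg": s.pcg_seg,
                    "coupling": s.coupling_seg,
                }
                for m in MODALITIES:
                    img = render_mrp(channels[m], ecfg, modality=m, seg_id=s.seg_id)
                    dsets[m][i] = img.pixels.astype(np.float16)
        return [out]

    st.run("mrp", params, ["couple"], fn)
    return out


def _load_images(path: Path):
    with h5py.File(path, "r") as f:
        images = {m: f[m][...].astype(float) for m in MODALITIES}
        subject_ids = [s.decode() for s in f["subject_id"][...]]
        seg_ids = [s.decode() for s in f["seg_id"][...]]
        labels = f["label"][...].astype(int)
    return images, subject_ids, seg_ids, labels


def stage_encode(cfg: PipelineConfig, st: _Stages) -> Path:
    img_path = st.run_dir / "images.h5"
    out = st.run_dir / "codes.h5"
    params = {
        "mode": cfg.encoder_mode,
        "width_divisor": cfg.width_divisor,
        "projection_dim": cfg.projection_dim,
        "epochs": cfg.encoder_epochs,
        "seed": cfg.seed,
        "cv_folds": cfg.cv_folds,
        "checkpoint": cfg.checkpoint,
    }

    def fn():
        spec = cfg.branch_spec()
        images, subject_ids, seg_ids, labels = _load_images(img_path)
        with h5py.File(out, "w") as f:
            f.attrs["mode"] = cfg.encoder_mode
            f.attrs["width_divisor"] = cfg.width_divisor
            f.attrs["projection_dim"] = cfg.projection_dim
            f.create_dataset("subject_id", data=np.array(subject_ids, dtype="S"))
            f.create_dataset("seg_id", data=np.array(seg_ids, dtype="S"))
            f.create_dataset("label", data=labels)
            if cfg.encoder_mode == "trained":
                _encode_trained_per_fold(cfg, spec, images, subject_ids, labels, f)
            else:
                weights = _shared_weights(cfg, spec)
                for i, m in enumerate(MODALITIES):
                    rng = np.random.default_rng(cfg.seed + 1000 + i)
                    f.create_dataset(
                        m, data=de.encode_images(images[m], spec, weights[m], rng)
                    )
        return [out]

    st.run("encode", params, ["mrp"], fn)
    return out


def _shared_weights(cfg: PipelineConfig, spec: de.BranchSpec) -> dict:
    if cfg.encoder_mode == "pretrained":
        if not cfg.checkpoint:
            raise ValueError("pretrained mode requires a checkpoint path")
        return de.load_weights(cfg.checkpoint, spec)
    return {
        m: de.init_branch_weights(spec, np.random.default_rng(cfg.seed + i))
        for i, m in enumerate(MODALITIES)
    }


def _encode_trained_per_fold(cfg, spec, images, subject_ids, labels, h5out) -> None:
    """Per-fold branch training: evaluation-fold images never touch the weights."""
    from .select_classify import make_folds

    subj_label = {}
    for sid, lab in zip(subject_ids, labels):
        subj_label[sid] = int(lab)
    assignment = make_folds(sorted(subj_label.items()), k=cfg.cv_folds, seed=cfg.seed)
    fold_of_row = np.array([assignment[s] for s in subject_ids])
    h5out.create_dataset("fold_of_row", data=fold_of_row)
    for m in MODALITIES:
        h5out.create_dataset(
            m,
            shape=(cfg.cv_folds, len(subject_ids), cfg.projection_dim),
            dtype="float64",
        )
    for fold in range(cfg.cv_folds):
        tr = fold_of_row != fold
        tcfg = de.TrainConfig(epochs=cfg.encoder_epochs, seed=cfg.seed * 100 + fold)
        weights = de.train_branches(
            {m: images[m][tr] for m in MODALITIES}, labels[tr], spec, tcfg
        )
        for i, m in enumerate(MODALITIES):
            rng = np.random.default_rng(cfg.seed + 2000 + fold * 10 + i)
            h5out[m][fold] = de.encode_images(images[m], spec, weights[m], rng)


def load_codes(path: Path):
    with h5py.File(path, "r") as f:
        codes = {m: f[m][...] for m in MODALITIES}
        subject_ids = [s.decode() for s in f["subject_id"][...]]
        labels = f["label"][...].astype(int)
        per_fold = "fold_of_row" in f
    return codes, subject_ids, labels, per_fold


def make_ae_compressor(block_dims: list[int], ae_widths: tuple, ae_epochs: int):
    """Per-fold compressor: one autoencoder per modality block, trained on the
    training rows only; returns a transform mapping deep codes to fused latents."""

    def compressor(train_X: np.ndarray, train_y: np.ndarray, fold_seed: int):
        bounds = np.cumsum([0] + block_dims)
        fitted = []
        for b in range(len(block_dims)):
            blk = train_X[:, bounds[b] : bounds[b + 1]]
            # standardize deep codes on the training fold before autoencoding:
            # unit-scale inputs keep SGD well-conditioned across modalities
            mu, sd = blk.mean(axis=0), blk.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            acfg = AEConfig(
                layer_widths=ae_widths, epochs=ae_epochs, seed=fold_seed + b
            )
            w, _ = train_autoencoder((blk - mu) / sd, acfg)
            fitted.append((mu, sd, w))

        def transform(X: np.ndarray) -> np.ndarray:
            parts = [
                ae_encode((X[:, bounds[b] : bounds[b + 1]] - mu) / sd, w)
                for b, (mu, sd, w) in enumerate(fitted)
            ]
            return np.concatenate(parts, axis=1)

        return transform

    return compressor


def classify_codes(
    cfg: PipelineConfig,
    codes: dict[str, np.ndarray],
    subject_ids: list[str],
    labels: np.ndarray,
    modalities: tuple = MODALITIES,
    per_fold: bool = False,
    permute_labels: bool = False,
) -> CVReport:
    """Autoencoder compression + SVM-RFE classification of deep codes."""
    mods = [m for m in MODALITIES if m in modalities]
    if not mods:
        raise ValueError("empty modality subset")
    if per_fold:
        X = None
        pff = np.concatenate([codes[m] for m in mods], axis=2)
        features = pff[0] * 0.0  # placeholder, shapes only
    else:
        pff = None
        X = np.concatenate([codes[m] for m in mods], axis=1)
        features = X
    y = labels.copy()
    if permute_labels:
        # permute at the subject level so segments of one subject stay consistent
        rng = np.random.default_rng(cfg.seed + 77)
        lab_of = dict(zip(subject_ids, labels))
        sids = sorted(lab_of)
        perm = dict(zip(sids, rng.permutation([lab_of[s] for s in sids])))
        y = np.array([perm[s] for s in subject_ids], dtype=int)
    compressor = make_ae_compressor(
        [codes[m].shape[-1] for m in mods], cfg.ae_widths, cfg.ae_epochs
    )
    return run_cv(
        features,
        y,
        subject_ids,
        grid=GridSpec(),
        k=cfg.cv_folds,
        seed=cfg.seed,
        rfe_step=cfg.rfe_step,
        compressor=compressor,
        per_fold_features=pff,
    )


def _report_to_dict(report: CVReport) -> dict:
    return {
        "folds": [
            {
                "fold": fr.fold,
                "metrics": fr.metrics,
                "counts": dataclasses.asdict(fr.counts),
                "selected_k": fr.selected_k,
                "hyperparams": list(fr.hyperparams),
            }
            for fr in report.folds
        ],
        "mean": report.mean,
        "std": report.std,
        "fold_subjects": report.fold_subjects,
    }


def _report_from_dict(d: dict) -> CVReport:
    from .select_classify import ConfusionCounts, FoldResult

    report = CVReport(mean=d["mean"], std=d["std"], fold_subjects=d["fold_subjects"])
    for fr in d["folds"]:
        report.folds.append(
            FoldResult(
                fold=fr["fold"],
                counts=ConfusionCounts(**fr["counts"]),
                metrics=fr["metrics"],
                selected_k=fr["selected_k"],
                selected_features=np.array([]),
                hyperparams=tuple(fr["hyperparams"]),
            )
        )
    return report


def stage_classify(cfg: PipelineConfig, st: _Stages) -> CVReport:
    codes_path = st.run_dir / "codes.h5"
    out = st.run_dir / "report.json"
    params = {
        "ae_widths": list(cfg.ae_widths),
        "ae_epochs": cfg.ae_epochs,
        "cv_folds": cfg.cv_folds,
        "rfe_step": cfg.rfe_step,
        "seed": cfg.seed,
    }
    holder: dict = {}

    def fn():
        codes, subject_ids, labels, per_fold = load_codes(codes_path)
        report = classify_codes(
            cfg, codes, subject_ids, labels, per_fold=per_fold
        )
        holder["report"] = report
        out.write_text(json.dumps(_report_to_dict(report), indent=2))
        return [out]

    ran = st.run("classify", params, ["encode"], fn)
    if not ran:
        holder["report"] = _report_from_dict(json.loads(out.read_text()))
    return holder["report"]


def stage_featurestats(cfg: PipelineConfig, st: _Stages) -> Path:
    """Descriptive feature analysis (not part of the CV classification path):
    autoencoders fitted on all segments, per-feature tests, correlation maps."""
    import pandas as pd

    codes_path = st.run_dir / "codes.h5"
    out_dir = st.run_dir / "stats"
    params = {"ae_widths": list(cfg.ae_widths), "ae_epochs": cfg.ae_epochs, "seed": cfg.seed}

    def fn():
        out_dir.mkdir(exist_ok=True)
        codes, subject_ids, labels, per_fold = load_codes(codes_path)
        if per_fold:
            codes = {m: codes[m][0] for m in MODALITIES}
        latents, results, rankings = {}, {}, {}
        for i, m in enumerate(MODALITIES):
            acfg = AEConfig(
                layer_widths=cfg.ae_widths, epochs=cfg.ae_epochs, seed=cfg.seed + i
            )
            w, _ = train_autoencoder(codes[m], acfg)
            latents[m] = ae_encode(codes[m], w)
            results[m] = fstats.test_features(latents[m], labels)
            keep = latents[m].std(axis=0) > 0
            ranking = np.full(latents[m].shape[1], latents[m].shape[1], dtype=int)
            if keep.sum() >= 2:
                sub = rfe_rank(latents[m][:, keep], labels)
                ranking[keep] = sub
            rankings[m] = ranking
        rows = []
        for m in MODALITIES:
            for r in results[m]:
                rows.append(
                    {
                        "modality": m,
                        "feature_index": r.feature_index,
                        "test_used": r.test_used,
                        "p_value": r.p_value,
                        "significant": r.significant,
                    }
                )
        tsv = out_dir / "feature_tests.tsv"
        pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False)
        top = fstats.top_k_features(results, rankings, k=5)
        top_tsv = out_dir / "top_features.tsv"
        pd.DataFrame(top).to_csv(top_tsv, sep="\t", index=False)
        corrs = fstats.modality_correlations(latents)
        fstats.plot_correlation_heatmaps(corrs, out_dir)
        return [tsv, top_tsv]

    st.run("featurestats", params, ["encode"], fn)
    return out_dir


def run_pipeline(cfg: PipelineConfig, with_stats: bool = True) -> CVReport:
    """Execute all stages in order; cached stages are skipped."""
    run_dir = Path(cfg.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    st = _Stages(run_dir)
    manifest = stage_synth(cfg, st)
    stage_preprocess(cfg, st, manifest)
    stage_couple(cfg, st)
    stage_mrp(cfg, st)
    stage_encode(cfg, st)
    report = stage_classify(cfg, st)
    if with_stats:
        stage_featurestats(cfg, st)
    return report


def ablate_modalities(
    cfg: PipelineConfig, subsets: list[tuple[str, ...]] | None = None
) -> dict[str, dict]:
    """CV reports per modality subset (single modalities + full fusion).

    Requires the encode stage to have run; reuses its deep codes.
    """
    run_dir = Path(cfg.run_dir)
    codes_path = run_dir / "codes.h5"
    if not codes_path.exists():
        raise FileNotFoundError("run the pipeline first (codes.h5 missing)")
    subsets = subsets or [("ecg",), ("pcg",), ("coupling",), MODALITIES]
    codes, subject_ids, labels, per_fold = load_codes(codes_path)
    out = {}
    for subset in subsets:
        if not subset:
            raise ValueError("empty modality subset")
        name = "+".join(subset)
        report = classify_codes(
            cfg, codes, subject_ids, labels, modalities=tuple(subset), per_fold=per_fold
        )
        out[name] = _report_to_dict(report)
    (run_dir / "ablation.json").write_text(json.dumps(out, indent=2))
    return out
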