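"""End-to-end workflow: normalize → register → train → evaluate.

Runs the four-step synthetic-CT workflow on a phantom cohort from a single
config: cohort generation, random train/test split, MR standardization
(standard scale fitted on training subjects only), optional rigid
registration of each MR to its CT, U-net training on the training split and
tissue-stratified evaluation of the held-out subjects.  Every stage is
seeded from one master seed, and artifacts carry the config and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluate as ev
from . import normalize as nz
from .grids import ImageGrid
from .phantom import CohortTemplate, PhantomPair, cohort
from .register import RigidTransform2D, register_rigid, warp
from .unet import TrainCfg, TrainedModel, UNetConfig, build_unet, predict, train

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """One config for the whole workflow."""

    template: CohortTemplate = field(default_factory=CohortTemplate)
    n_subjects: int = 33
    split: tuple[float, float] = (0.7, 0.3)
    caps: tuple[float, float] = nz.DEFAULT_CAPS
    unet: UNetConfig = field(default_factory=UNetConfig)
    train: TrainCfg = field(default_factory=TrainCfg)
    registration: str = "auto"  # none | rigid | auto
    misalignment_scope: str = "all"  # all | train_only
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.registration not in ("none", "rigid", "auto"):
            raise ValueError("registration must be 'none', 'rigid' or 'auto'")
        if self.misalignment_scope not in ("all", "train_only"):
            raise ValueError("misalignment_scope must be 'all' or 'train_only'")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.unet.input_size != self.template.image_size:
            raise ValueError("unet.input_size must equal template.image_size")

    # -- config I/O --------------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        phantom_d = dict(d.pop("phantom", {}))
        mis = phantom_d.pop("misalignment", None)
        if mis is not None:
            mis = RigidTransform2D(mis.get("rotation", 0.0),
                                   tuple(mis.get("translation", (0.0, 0.0))))
        template = CohortTemplate(misalignment=mis, **phantom_d)
        unet_d = dict(d.pop("unet", {}))
        unet_d.setdefault("input_size", template.image_size)
        kwargs = dict(
            template=template,
            unet=UNetConfig(**unet_d),
            train=TrainCfg(**d.pop("train", {})),
        )
        for k in ("n_subjects", "split", "caps", "registration",
                  "misalignment_scope", "seed", "outdir"):
            if k in d:
                v = d.pop(k)
                kwargs[k] = tuple(v) if k in ("split", "caps") else v
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        mis = self.template.misalignment
        d["template"]["misalignment"] = None if mis is None else {
            "rotation": mis.rotation, "translation": list(mis.translation)}
        return d


@dataclass
class PipelineResult:
    report: ev.EvalReport
    baseline_report: ev.EvalReport
    model: TrainedModel
    standard_scale: nz.StandardScale
    train_subjects: list[int]
    test_subjects: list[int]
    meta: dict


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def split_cohort(subjects: list, fractions: tuple[float, float],
                 seed: int) -> tuple[list, list]:
    """Random disjoint, exhaustive train/test split.

    Train size = round(n × train_fraction), so 33 subjects at (0.7, 0.3)
    give the 23/10 split.  Reproducible from the seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(subjects)
    n_train = int(round(n * fractions[0]))
    perm = np.random.default_rng(seed).permutation(n)
    train_idx = sorted(perm[:n_train].tolist())
    test_idx = sorted(perm[n_train:].tolist())
    return [subjects[i] for i in train_idx], [subjects[i] for i in test_idx]


def _derived_seeds(master: int, n: int = 4) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(master).spawn(n)]


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and return the held-out evaluation report."""
    t_start = time.perf_counter()
    cohort_seed, split_seed, train_seed, _ = _derived_seeds(config.seed)
    meta: dict = {"seed": config.seed,
                  "derived_seeds": {"cohort": cohort_seed, "split": split_seed,
                                    "train": train_seed},
                  "stages": {}}

    def stage(name):
        meta["stages"][name] = {"t0": time.perf_counter() - t_start}
        log.info("stage %s ...", name)

    def done(name):
        meta["stages"][name]["seconds"] = (
            time.perf_counter() - t_start - meta["stages"][name].pop("t0"))

    stage("cohort")
    template = config.template
    train_only_mis = (config.misalignment_scope == "train_only"
                      and template.misalignment is not None)
    if train_only_mis:
        # generate aligned pairs; the misalignment is injected into the
        # training subjects below so held-out evaluation stays aligned
        mis = template.misalignment
        template = dataclasses.replace(template, misalignment=None)
    pairs = cohort(template, config.n_subjects, cohort_seed)
    done("cohort")

    stage("split")
    idx_train, idx_test = split_cohort(list(range(config.n_subjects)),
                                       config.split, split_seed)
    train_pairs = [pairs[i] for i in idx_train]
    test_pairs = [pairs[i] for i in idx_test]
    if train_only_mis:
        train_pairs = [
            PhantomPair(ct=p.ct, mr=warp(p.mr, mis), labels=p.labels,
                        true_misalignment=mis, spec=p.spec,
                        empty_tissues=p.empty_tissues)
            for p in train_pairs]
    done("split")

    stage("register")
    misaligned = any(not p.true_misalignment.is_identity
                     for p in train_pairs + test_pairs)
    do_register = (config.registration == "rigid"
                   or (config.registration == "auto" and misaligned))
    if do_register:
        train_pairs = [_register_pair(p) for p in train_pairs]
        test_pairs = [_register_pair(p) for p in test_pairs]
    done("register")
    meta["registered"] = bool(do_register)

    stage("normalize")
    std, train_mr = nz.standardize_cohort([p.mr for p in train_pairs],
                                          caps=config.caps)
    test_mr = [nz.apply_standardization(
        p.mr, nz.compute_landmarks(p.mr, caps=config.caps), std)
        for p in test_pairs]
    meta["standard_scale"] = {"fitted_on": "train_subjects_only",
                              "n_train": len(train_pairs),
                              "fingerprint": std.fingerprint()}
    done("normalize")

    stage("train")
    train_cfg = dataclasses.replace(config.train, seed=train_seed)
    model = build_unet(config.unet)
    fitted = train(model, [(mr, p.ct) for mr, p in zip(train_mr, train_pairs)],
                   train_cfg, standard_scale_fingerprint=std.fingerprint())
    done("train")

    stage("evaluate")
    scts = [predict(fitted, mr) for mr in test_mr]
    report = ev.cohort_report([(p.ct, s) for p, s in zip(test_pairs, scts)])
    train_mean_hu = float(np.mean([p.ct.data for p in train_pairs]))
    baseline = ev.cohort_report(
        [(p.ct, p.ct.with_data(np.full(p.ct.shape, train_mean_hu)))
         for p in test_pairs])
    meta["train_mean_hu"] = train_mean_hu
    done("evaluate")
    meta["total_seconds"] = time.perf_counter() - t_start

    result = PipelineResult(report=report, baseline_report=baseline,
                            model=fitted, standard_scale=std,
                            train_subjects=idx_train, test_subjects=idx_test,
                            meta=meta)
    if config.outdir:
        _write_artifacts(config, result, test_pairs, test_mr, scts)
    return result


def _register_pair(pair: PhantomPair) -> PhantomPair:
    """Rigidly align the MR to its CT and resample it."""
    res = register_rigid(pair.ct, pair.mr)
    mr_aligned = warp(pair.mr, res.transform)
    mr_aligned.meta["registration"] = {
        "rotation": res.transform.rotation,
        "translation": list(res.transform.translation),
        "mi": res.metric, "low_confidence": res.low_confidence}
    return PhantomPair(ct=pair.ct, mr=mr_aligned, labels=pair.labels,
                       true_misalignment=pair.true_misalignment,
                       spec=pair.spec, empty_tissues=pair.empty_tissues)


def _write_artifacts(config: PipelineConfig, result: PipelineResult,
                     test_pairs: list[PhantomPair], test_mr: list[ImageGrid],
                     scts: list[ImageGrid]) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    (out / "run_meta.json").write_text(json.dumps(result.meta, indent=2))
    nz.save_scale(result.standard_scale, out / "standard_scale.json")
    result.report.to_csv(out / "report.csv")
    result.baseline_report.to_csv(out / "baseline_report.csv")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    for i, (pair, mr, sct) in enumerate(zip(test_pairs, test_mr, scts)):
        sid = f"test_{i + 1:02d}"
        sct.to_nifti(out / f"{sid}_sct.nii.gz")
        fig, axes = plt.subplots(1, 4, figsize=(12, 3))
        panels = [(mr.data, "standardized MR"), (pair.ct.data, "true CT"),
                  (sct.data, "synthetic CT"),
                  (np.abs(pair.ct.data - sct.data), "|CT − sCT|")]
        for ax, (img, title) in zip(axes, panels):
            ax.imshow(img, cmap="gray")
            ax.set_title(title, fontsize=9)
            ax.axis("off")
        fig.savefig(out / f"{sid}_panel.png", dpi=100, bbox_inches="tight")
        plt.close(fig)
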