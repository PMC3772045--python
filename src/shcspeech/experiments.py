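"""Desk-scale experiment runners with config, logging and CSV/JSON output.

Each runner reproduces one study condition end to end on synthetic
stimuli: word learning speed, word recognition across SNRs, rate
(time-compression) invariance, cocktail-party mixtures, accent
adaptation across precision ratios, and second-language-style learning
groups.  Every runner echoes its configuration, seeds all randomness,
and writes machine-readable results (JSON summary + CSV tables) to the
output directory; reruns with the same config are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .agent import Agent, average_modules, classify, train_module
from .cochlea import denoise, rescale_time, time_compress
from .dynamics import GenerativeModel, SimulationConfig, simulate_hierarchy
from .inference import (
    InferenceSettings,
    PrecisionConfig,
    error_summary,
    infer_states,
    learn_feedback,
    recognition_accuracy,
)
from .synth import (
    DatasetSpec,
    SyntheticWordSpec,
    accent_perturb,
    add_noise,
    make_class_specs,
    make_dataset,
    make_word,
    mix_speakers,
)

__all__ = [
    "ExperimentConfig",
    "run_learning",
    "run_recognition",
    "run_compression",
    "run_cocktail",
    "run_accent",
    "run_l2",
]

log = logging.getLogger("shcspeech")


@dataclass
class ExperimentConfig:
    """Shared configuration of the experiment runners.

    Dataset sizes default to a desk-scale layout (10 classes, 5
    speakers, 2 tokens each) so a full run stays in the minutes range;
    the corpus-scale layout is 10 x 5 x 10.
    """

    name: str = "experiment"
    n_classes: int = 10
    n_speakers: int = 5
    tokens_per_speaker: int = 2
    n_train: int = 1
    n_test: int = 1
    snr_list: tuple = (30.0, 20.0, 10.0)
    denoise_quantile: float = 0.5
    compress_factor: float = 0.75
    distractor_counts: tuple = (0, 1, 3)
    distractor_gain: float = 0.5
    ratio_grid: tuple = (-6.0, -4.0, -2.0, 0.0, 2.0, 4.0, 6.0)
    ratio_level_sum: float = 10.0
    accent_magnitude: float = 0.25
    adapt_reps: int = 5
    l2_groups: tuple = (
        ("native", 4.0),
        ("early", 1.0),
        ("mid", -1.0),
        ("late", -3.0),
    )
    l2_snr_list: tuple = (-30.0, 0.0, 10.0, 20.0, 30.0)
    seed: int = 0
    n_inner: int = 2
    n_inner_learning: int = 4
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("snr_list", "distractor_counts", "ratio_grid", "l2_snr_list"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "l2_groups" in raw:
            raw["l2_groups"] = tuple((g[0], float(g[1])) for g in raw["l2_groups"])
        return cls(**raw)

    def settings(self) -> InferenceSettings:
        return InferenceSettings(n_inner=self.n_inner)

    def learning_settings(self) -> InferenceSettings:
        # parameter learning benefits from finer gradient-flow integration
        return InferenceSettings(n_inner=self.n_inner_learning)

    def dataset_spec(self) -> DatasetSpec:
        return DatasetSpec(
            n_classes=self.n_classes,
            n_speakers=self.n_speakers,
            tokens_per_speaker=self.tokens_per_speaker,
            master_seed=self.seed,
        )


def _out_dir(cfg: ExperimentConfig, default: str) -> Optional[Path]:
    if cfg.out_dir is None:
        return None
    p = Path(cfg.out_dir) / default
    p.mkdir(parents=True, exist_ok=True)
    return p


def _emit(out: Optional[Path], cfg: ExperimentConfig, report: dict, tables: dict) -> None:
    if out is None:
        return
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=1, default=list)
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    for name, rows in tables.items():
        pd.DataFrame(rows).to_csv(out / f"{name}.csv", index=False)


def _train_split_agent(cfg: ExperimentConfig, settings: InferenceSettings):
    """Train per-token modules on the split's training half, average within
    class, return (agent, test tokens)."""
    train_st = cfg.learning_settings()
    tokens, _ = make_dataset(cfg.dataset_spec())
    rng = np.random.default_rng(cfg.seed + 1)
    groups: dict = {}
    for tok in tokens:
        groups.setdefault((tok.label, tok.speaker), []).append(tok)
    train_toks, test_toks = [], []
    for key in sorted(groups):
        toks = groups[key]
        order = rng.permutation(len(toks))
        train_toks += [toks[i] for i in order[: cfg.n_train]]
        test_toks += [toks[i] for i in order[cfg.n_train : cfg.n_train + cfg.n_test]]
    by_label: dict = {}
    for tok in train_toks:
        by_label.setdefault(tok.label, []).append(tok)
    modules = []
    for label in sorted(by_label, key=lambda s: (len(s), s)):
        per_token = [
            train_module(label, [tok.stimulus], settings=train_st)
            for tok in by_label[label]
        ]
        modules.append(average_modules(per_token))
        log.info("%s: trained %d modules for class %s", cfg.name, len(per_token), label)
    return Agent(modules=modules), test_toks


def run_learning(cfg: ExperimentConfig) -> dict:
    """Word-learning speed: convergence repetitions per word + overlays.

    Trains one fresh module per word token under the learning preset and
    reports the distribution of repetitions to convergence; a control
    under the (non-learning) recognition preset shows no convergence.
    Also emits a regenerated-vs-input channel overlay for the first word
    (the read-out of the learned internal model).
    """
    from .dynamics import default_model

    st = cfg.learning_settings()
    specs = make_class_specs(cfg.n_classes, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 10)
    rows, convs = [], []
    overlay = None
    for spec in specs:
        z = make_word(spec, token_seed=int(rng.integers(2**31)))
        m = default_model()
        curve_rec = learn_feedback(m, PrecisionConfig.learning(), z, settings=st)
        conv = curve_rec.converged_at or len(curve_rec.error_curve)
        convs.append(conv)
        rows.append(
            {
                "label": spec.label,
                "converged_at": conv,
                "final_error": curve_rec.error_curve[-1],
                "initial_error": curve_rec.error_curve[0],
            }
        )
        if overlay is None:
            out, _ = simulate_hierarchy(m, SimulationConfig(T=z.T, seed=0))
            overlay = {"input": z.values, "generated": out}
    # control: recognition preset must not adapt
    z0 = make_word(specs[0], token_seed=123)
    m = default_model()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctrl = learn_feedback(m, PrecisionConfig.noisy_recognition(), z0, max_reps=6,
                              settings=st)
    ctrl_drop = (
        (ctrl.error_curve[0] - ctrl.error_curve[-1]) / ctrl.error_curve[0]
        if ctrl.error_curve
        else 0.0
    )
    report = {
        "median_convergence": float(np.median(convs)),
        "convergence_reps": convs,
        "control_relative_drop": float(ctrl_drop),
        "seed": cfg.seed,
    }
    out = _out_dir(cfg, "learning")
    tables = {"convergence": rows}
    if out is not None and overlay is not None:
        ov = pd.DataFrame(
            np.vstack([overlay["input"], overlay["generated"]]).T,
            columns=[f"input_ch{i}" for i in range(6)]
            + [f"generated_ch{i}" for i in range(6)],
        )
        ov.to_csv(out / "overlay.csv", index=False)
    _emit(out, cfg, report, tables)
    return report


def _classify_set(agent, test_toks, pc, st, transform=None):
    rows, wrong = [], 0
    for tok in test_toks:
        z = tok.stimulus if transform is None else transform(tok.stimulus)
        res = classify(agent, z, pc=pc, settings=st)
        ok = res.predicted == tok.label
        wrong += not ok
        rows.append(
            {
                "label": tok.label,
                "speaker": tok.speaker,
                "predicted": res.predicted,
                "correct": bool(ok),
                "margin": res.margin,
            }
        )
    wer = wrong / len(test_toks) if test_toks else 0.0
    return wer, rows


def run_recognition(cfg: ExperimentConfig) -> dict:
    """WER on held-out tokens, clean and across the SNR ladder.

    Modules are trained once on clean tokens; noisy conditions only
    transform the test input (additive channel noise at the target SNR
    followed by cochleagram-level quantile denoising) and switch the
    agent to the noisy-recognition precision preset.
    """
    st = cfg.settings()
    agent, test_toks = _train_split_agent(cfg, st)
    report, tables = {"seed": cfg.seed, "wer": {}}, {}
    wer, rows = _classify_set(
        agent, test_toks, PrecisionConfig.clean_recognition(), st
    )
    report["wer"]["clean"] = wer
    tables["clean"] = rows
    noise_rng = np.random.default_rng(cfg.seed + 2)
    for snr in cfg.snr_list:
        seed0 = int(noise_rng.integers(2**31))

        def noisy(z, snr=snr, seed0=seed0):
            zn = add_noise(z, snr, seed=seed0)
            return denoise(zn, cfg.denoise_quantile)

        wer, rows = _classify_set(
            agent, test_toks, PrecisionConfig.noisy_recognition(), st, transform=noisy
        )
        report["wer"][f"{snr:g}dB"] = wer
        tables[f"snr_{snr:g}"] = rows
        log.info("%s: WER %.3f at %g dB", cfg.name, wer, snr)
    _emit(_out_dir(cfg, "recognition"), cfg, report, tables)
    return report


def run_compression(cfg: ExperimentConfig) -> dict:
    """Classify time-compressed held-out tokens with unmodified modules."""
    st = cfg.settings()
    agent, test_toks = _train_split_agent(cfg, st)
    pc = PrecisionConfig.clean_recognition()
    report, tables = {"seed": cfg.seed}, {}
    wer0, rows0 = _classify_set(agent, test_toks, pc, st)

    def compress(z):
        return rescale_time(time_compress(z, cfg.compress_factor).values, z.T)

    werc, rowsc = _classify_set(agent, test_toks, pc, st, transform=compress)
    report["accuracy_uncompressed"] = 100.0 * (1 - wer0)
    report["accuracy_compressed"] = 100.0 * (1 - werc)
    report["compress_factor"] = cfg.compress_factor
    tables["uncompressed"], tables["compressed"] = rows0, rowsc
    _emit(_out_dir(cfg, "compression"), cfg, report, tables)
    return report


def _order_recovery(mu_v2: np.ndarray) -> float:
    """Fraction of the expected 1..N visit order recovered (longest common
    subsequence of the dominance order with 1..N, over N)."""
    N = mu_v2.shape[0]
    dom = np.argmax(mu_v2, axis=0)
    order = [int(k) for k, _ in __import__("itertools").groupby(dom)]
    target = list(range(N))
    # LCS(order, target)
    dp = np.zeros((len(order) + 1, N + 1), dtype=int)
    for i, o in enumerate(order):
        for j, t in enumerate(target):
            dp[i + 1, j + 1] = (
                dp[i, j] + 1 if o == t else max(dp[i, j + 1], dp[i + 1, j])
            )
    return dp[-1, -1] / N


def run_cocktail(cfg: ExperimentConfig) -> dict:
    """Sentence-length module vs 0/1/3 concurrent background speakers.

    A 16-segment "sentence" (two concatenated words) is learned by an
    N = 16 module; mixtures add distractor sentences at the configured
    gain.  Reports second-level order-recovery and per-level error
    totals per condition.
    """
    st = cfg.settings()
    specs = make_class_specs(max(cfg.n_classes, 8), seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 3)

    def sentence(a, b, label):
        profiles = np.vstack(
            [specs[a].segment_profiles, specs[b].segment_profiles]
        )
        return SyntheticWordSpec(label=label, segment_profiles=profiles)

    target_spec = sentence(0, 1, "target")
    distractor_specs = [sentence(2, 3, "d1"), sentence(4, 5, "d2"), sentence(6, 7, "d3")]
    z_target = make_word(target_spec, token_seed=int(rng.integers(2**31)))
    z_distract = [
        make_word(s, token_seed=int(rng.integers(2**31))) for s in distractor_specs
    ]
    mod = train_module("target", [z_target], N=16, settings=cfg.learning_settings())
    # strong bottom-up (level-1 hidden) weight so degraded input leaves a
    # second-level signature rather than the sequencer free-running
    pc = PrecisionConfig(logpi_v1=4.0, logpi_x1=8.0, logpi_v2=4.0, logpi_x2=4.0)
    report, rows = {"seed": cfg.seed, "conditions": {}}, []
    clean_dom = None
    for k in cfg.distractor_counts:
        z = mix_speakers(
            z_target, z_distract[:k], gains=[cfg.distractor_gain] * k
        )
        traj = infer_states(mod.model, pc, z, settings=st)
        es = error_summary(traj)
        rec = _order_recovery(traj.mu_v2)
        dom = np.argmax(traj.mu_v2, axis=0)
        if clean_dom is None:
            clean_dom = dom
        agreement = float(np.mean(dom == clean_dom))
        report["conditions"][str(k)] = {
            "order_recovery": rec,
            "clean_agreement": agreement,
            "err_v1": es["v1"],
            "err_x1": es["x1"],
            "err_v2": es["v2"],
            "err_x2": es["x2"],
        }
        rows.append({"distractors": k, "order_recovery": rec,
                     "clean_agreement": agreement,
                     **{f"err_{c}": es[c] for c in ("v1", "x1", "v2", "x2")}})
        log.info("%s: %d distractors -> order recovery %.2f agreement %.2f",
                 cfg.name, k, rec, agreement)
    _emit(_out_dir(cfg, "cocktail"), cfg, report, {"conditions": rows})
    return report


def run_accent(cfg: ExperimentConfig) -> dict:
    """Adapt pre-trained modules to accent-perturbed words across a grid
    of first-level sensory/internal precision ratios.

    Adaptation quality is measured precision-free: the relative reduction
    in mean squared error between the module's regenerated output (the
    read-out of its internal model) and the accented stimulus, before
    vs after adaptation.  Iterations-to-adapt is the repetition at which
    the accumulated learning error could be no further reduced.
    """
    st = cfg.learning_settings()
    specs = make_class_specs(3, seed=cfg.seed)
    half = cfg.ratio_level_sum / 2.0
    rows = []

    def regen_mse(model, z):
        out, _ = simulate_hierarchy(model, SimulationConfig(T=z.T, seed=0))
        return float(np.mean((out - z.values) ** 2))

    for w, spec in enumerate(specs):
        base_mod = train_module(spec.label, [make_word(spec, token_seed=w + 1)],
                                settings=st)
        acc = accent_perturb(spec, cfg.accent_magnitude, seed=cfg.seed + w)
        z_acc = make_word(acc, token_seed=100 + w)
        mse_pre = regen_mse(base_mod.model, z_acc)
        for r in cfg.ratio_grid:
            pca = PrecisionConfig(
                logpi_v1=half + r / 2.0,
                logpi_x1=half - r / 2.0,
                logpi_v2=7.0,
                logpi_x2=7.0,
            )
            m = GenerativeModel.from_dict(base_mod.model.to_dict())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rec = learn_feedback(
                    m, pca, z_acc, max_reps=cfg.adapt_reps, settings=st
                )
            mse_post = regen_mse(m, z_acc)
            rows.append(
                {
                    "word": spec.label,
                    "ratio": r,
                    "mse_pre": mse_pre,
                    "mse_post": mse_post,
                    "reduction_pct": 100.0 * (mse_pre - mse_post) / mse_pre,
                    "iters_to_adapt": rec.converged_at,
                }
            )
    df = pd.DataFrame(rows)
    by_ratio = df.groupby("ratio")["reduction_pct"].mean()
    top = max(cfg.ratio_grid)
    top_iters = [
        r["iters_to_adapt"]
        for r in rows
        if r["ratio"] == top and r["iters_to_adapt"] is not None
    ]
    report = {
        "seed": cfg.seed,
        "reduction_by_ratio": {f"{k:g}": float(v) for k, v in by_ratio.items()},
        "iters_to_adapt_top_ratio": (
            float(np.median(top_iters)) if top_iters else None
        ),
    }
    _emit(_out_dir(cfg, "accent"), cfg, report, {"sweep": rows})
    return report


def run_l2(cfg: ExperimentConfig) -> dict:
    """Second-language-style groups: learn the vocabulary at group-specific
    precision ratios, test across an SNR ladder.

    Accuracy per group and SNR is the percent error reduction relative
    to that group's own -30 dB baseline condition, averaged over words
    (matched-module causal errors).
    """
    st = cfg.settings()
    specs = make_class_specs(cfg.n_classes, seed=cfg.seed)
    half = cfg.ratio_level_sum / 2.0
    pc_eval = PrecisionConfig.noisy_recognition()
    rng = np.random.default_rng(cfg.seed + 4)
    token_seeds = [int(rng.integers(2**31)) for _ in specs]
    noise_seeds = {snr: int(rng.integers(2**31)) for snr in cfg.l2_snr_list}
    baseline_snr = min(cfg.l2_snr_list)
    rows = []
    report = {"seed": cfg.seed, "accuracy": {}}
    for gname, ratio in cfg.l2_groups:
        pcg = PrecisionConfig(
            logpi_v1=half + ratio / 2.0,
            logpi_x1=half - ratio / 2.0,
            logpi_v2=7.0,
            logpi_x2=7.0,
        )
        mods = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, spec in enumerate(specs):
                mods.append(
                    train_module(spec.label, [make_word(spec, token_seed=token_seeds[i])],
                                 pc=pcg, settings=cfg.learning_settings())
                )
        errs_by_snr = {}
        for snr in cfg.l2_snr_list:
            errs = []
            for i, spec in enumerate(specs):
                z = make_word(spec, token_seed=token_seeds[i] + 1)
                zn = add_noise(z, snr, seed=noise_seeds[snr] + i)
                es = error_summary(
                    infer_states(mods[i].model, pc_eval, zn, settings=st)
                )
                errs.append(es["v1"])
            errs_by_snr[snr] = float(np.mean(errs))
        base_err = errs_by_snr[baseline_snr]
        accs = {
            f"{snr:g}dB": recognition_accuracy(base_err, errs_by_snr[snr])
            for snr in cfg.l2_snr_list
        }
        report["accuracy"][gname] = accs
        for snr in cfg.l2_snr_list:
            rows.append(
                {
                    "group": gname,
                    "ratio": ratio,
                    "snr": snr,
                    "mean_err": errs_by_snr[snr],
                    "accuracy": accs[f"{snr:g}dB"],
                }
            )
        log.info("%s: group %s accuracies %s", cfg.name, gname, accs)
    _emit(_out_dir(cfg, "l2"), cfg, report, {"groups": rows})
    return report
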