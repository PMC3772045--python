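"""Word-level machinery: modules, agents, classification, cross-validation.

A *module* is one learned word template: the shared hierarchical model
(fixed sequencer connectivity rho and first-level coupling W) plus the
feedback weights trained on tokens of a single word and the precision
settings it operates under.  An *agent* is a bank of modules, one per
word; classification presents a stimulus to every module concurrently
and picks the module with the least precision-weighted prediction error
(winner-take-all on the configured score channel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import GenerativeModel, default_model
from .inference import (
    InferenceSettings,
    DEFAULT_SETTINGS,
    PrecisionConfig,
    error_summary,
    infer_states,
    learn_feedback,
)

__all__ = [
    "WordModule",
    "Agent",
    "ClassificationResult",
    "train_module",
    "average_modules",
    "classify",
    "cross_validate",
]


@dataclass
class WordModule:
    """A learned template: model + trained feedback weights + precisions."""

    label: str
    model: GenerativeModel
    precisions: PrecisionConfig
    trained: bool = False

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "model": self.model.to_dict(),
            "precisions": vars(self.precisions).copy(),
            "trained": self.trained,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WordModule":
        return cls(
            label=d["label"],
            model=GenerativeModel.from_dict(d["model"]),
            precisions=PrecisionConfig(**d["precisions"]),
            trained=bool(d["trained"]),
        )


@dataclass
class Agent:
    """An ordered bank of word modules with unique labels."""

    modules: list

    def __post_init__(self) -> None:
        labels = [m.label for m in self.modules]
        if len(set(labels)) != len(labels):
            raise ValueError("module labels must be unique")

    @property
    def labels(self) -> list:
        return [m.label for m in self.modules]

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"modules": [m.to_dict() for m in self.modules]}, fh)

    @classmethod
    def load_json(cls, path) -> "Agent":
        with open(path) as fh:
            d = json.load(fh)
        return cls(modules=[WordModule.from_dict(md) for md in d["modules"]])


@dataclass
class ClassificationResult:
    """Winner-take-all outcome: label, per-module scores, winner margin."""

    predicted: str
    scores: dict
    margin: float


def train_module(
    label: str,
    stimuli,
    pc: Optional[PrecisionConfig] = None,
    N: int = 8,
    n: int = 6,
    settings: Optional[InferenceSettings] = None,
    max_reps: int = 16,
) -> WordModule:
    """Train one module on one or more tokens of a word.

    Tokens are learned sequentially, each continuing from the feedback
    weights left by the previous one (fine-tuning within a word).
    """
    stimuli = list(stimuli)
    if not stimuli:
        raise ValueError("at least one stimulus required")
    pc = pc or PrecisionConfig.learning()
    model = default_model(N=N, n=n)
    for z in stimuli:
        learn_feedback(model, pc, z, max_reps=max_reps, settings=settings)
    return WordModule(label=label, model=model, precisions=pc, trained=True)


def average_modules(modules) -> WordModule:
    """Element-wise mean of the feedback weights within one word class.

    All modules must share the label and model dimensions; everything
    except the averaged feedback weights is inherited from the first.
    """
    modules = list(modules)
    if not modules:
        raise ValueError("no modules to average")
    labels = {m.label for m in modules}
    if len(labels) != 1:
        raise ValueError(f"cannot average modules with mixed labels: {labels}")
    shapes = {m.model.fb.I.shape for m in modules}
    if len(shapes) != 1:
        raise ValueError("cannot average modules with mixed dimensions")
    first = modules[0]
    mean_I = np.mean([m.model.fb.I for m in modules], axis=0)
    model = GenerativeModel.from_dict(first.model.to_dict())
    model.fb.I = mean_I
    return WordModule(
        label=first.label,
        model=model,
        precisions=first.precisions,
        trained=all(m.trained for m in modules),
    )


def classify(
    agent: Agent,
    z,
    pc: Optional[PrecisionConfig] = None,
    settings: Optional[InferenceSettings] = None,
) -> ClassificationResult:
    """Present a stimulus to every module; the lowest score wins.

    Learning is off; each module filters the stimulus under ``pc`` (or
    its own stored precisions) and is scored by the configured error
    channel.  Ties break deterministically toward the lowest module
    index.
    """
    if not agent.modules:
        raise ValueError("agent has no modules")
    st = settings or DEFAULT_SETTINGS
    scores = {}
    best_idx, best = None, np.inf
    for idx, mod in enumerate(agent.modules):
        use_pc = pc or mod.precisions
        traj = infer_states(mod.model, use_pc, z, settings=st)
        s = error_summary(traj, score=st.score)["score"]
        scores[mod.label] = s
        if s < best:
            best, best_idx = s, idx
    ordered = sorted(scores.values())
    margin = (ordered[1] - ordered[0]) if len(ordered) > 1 else 0.0
    return ClassificationResult(
        predicted=agent.modules[best_idx].label, scores=scores, margin=margin
    )


def cross_validate(
    dataset,
    split_spec: Optional[dict] = None,
    pc_train: Optional[PrecisionConfig] = None,
    pc_test: Optional[PrecisionConfig] = None,
    seed: int = 0,
    settings: Optional[InferenceSettings] = None,
    max_reps: int = 16,
    transform=None,
):
    """Word-error-rate estimate with a per-class/per-speaker split.

    ``dataset`` is a list of :class:`shcspeech.synth.Token`;
    ``split_spec`` gives tokens per (class, speaker) for training and
    test (default ``{"n_train": 8, "n_test": 2}``).  Per-token modules
    are trained independently and averaged within class; the held-out
    tokens are classified by the averaged agent.  ``transform`` (if
    given) maps each held-out stimulus before classification, e.g. a
    noise or compression manipulation.  Returns a dict with the WER,
    confusion counts and per-token records; fully seeded.
    """
    split_spec = split_spec or {"n_train": 8, "n_test": 2}
    n_train, n_test = split_spec["n_train"], split_spec["n_test"]
    pc_train = pc_train or PrecisionConfig.learning()
    pc_test = pc_test or PrecisionConfig.clean_recognition()
    rng = np.random.default_rng(seed)

    groups: dict = {}
    for tok in dataset:
        groups.setdefault((tok.label, tok.speaker), []).append(tok)
    train_toks, test_toks = [], []
    for key in sorted(groups):
        toks = groups[key]
        if len(toks) < n_train + n_test:
            raise ValueError(
                f"class/speaker group {key} has {len(toks)} tokens; "
                f"need {n_train + n_test}"
            )
        order = rng.permutation(len(toks))
        train_toks += [toks[i] for i in order[:n_train]]
        test_toks += [toks[i] for i in order[n_train : n_train + n_test]]

    by_label: dict = {}
    for tok in train_toks:
        by_label.setdefault(tok.label, []).append(tok)
    modules = []
    for label in sorted(by_label, key=lambda s: (len(s), s)):
        per_token = [
            train_module(label, [tok.stimulus], pc_train, settings=settings,
                         max_reps=max_reps)
            for tok in by_label[label]
        ]
        modules.append(average_modules(per_token))
    agent = Agent(modules=modules)

    confusion: dict = {}
    records = []
    wrong = 0
    for tok in test_toks:
        z = tok.stimulus if transform is None else transform(tok.stimulus)
        res = classify(agent, z, pc=pc_test, settings=settings)
        ok = res.predicted == tok.label
        wrong += not ok
        confusion[(tok.label, res.predicted)] = (
            confusion.get((tok.label, res.predicted), 0) + 1
        )
        records.append(
            {
                "label": tok.label,
                "speaker": tok.speaker,
                "token": tok.token,
                "predicted": res.predicted,
                "correct": bool(ok),
                "margin": res.margin,
                **{f"score_{k}": v for k, v in res.scores.items()},
            }
        )
    wer = wrong / len(test_toks) if test_toks else 0.0
    return {
        "wer": wer,
        "n_test": len(test_toks),
        "confusion": {f"{a}->{b}": c for (a, b), c in sorted(confusion.items())},
        "records": records,
        "seed": seed,
        "agent": agent,
    }
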