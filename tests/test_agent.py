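"""Word modules, averaging, winner-take-all classification, WER."""

import numpy as np
import pytest

from shcspeech.agent import (
    Agent,
    WordModule,
    average_modules,
    classify,
    cross_validate,
    train_module,
)
from shcspeech.dynamics import SimulationConfig, simulate_hierarchy
from shcspeech.inference import InferenceSettings, PrecisionConfig
from shcspeech.synth import DatasetSpec, make_dataset, make_speakers, make_word

from conftest import FAST

TRAIN = InferenceSettings(n_inner=4)


@pytest.fixture(scope="module")
def small_agent(word_specs):
    """Agent with modules for the first four synthetic word classes."""
    mods = [
        train_module(word_specs[i].label, [make_word(word_specs[i], token_seed=21 + i)],
                     settings=TRAIN)
        for i in range(4)
    ]
    return Agent(modules=mods)


class TestTrainModule:
    def test_learned_module_regenerates_token(self, word_specs):
        """Generate-learn-regenerate: the learned internal model replays
        the trained token closely away from segment boundaries (and far
        more closely than it replays a different word)."""
        from shcspeech.synth import SyntheticWordSpec

        spec = SyntheticWordSpec(
            label="w",
            segment_profiles=word_specs[0].segment_profiles,
            boundary_jitter=0.0,
        )
        z = make_word(spec, token_seed=1)
        mod = train_module("w", [z], settings=TRAIN)
        out, _ = simulate_hierarchy(mod.model, SimulationConfig(T=100, seed=0))
        dev = np.abs(out - z.values)
        mask = np.ones(100, bool)
        for b in range(0, 100, 12):
            mask[b : b + 5] = False  # skip attractor-switching transients
        assert dev[:, mask].mean() < 0.08
        z_other = make_word(word_specs[1], token_seed=1)
        dev_other = np.abs(out - z_other.values)
        assert dev[:, mask].mean() < 0.5 * dev_other[:, mask].mean()

    def test_matched_module_beats_mismatched_on_fresh_token(self, word_specs):
        mod_a = train_module("a", [make_word(word_specs[0], token_seed=31)],
                             settings=TRAIN)
        mod_b = train_module("b", [make_word(word_specs[1], token_seed=32)],
                             settings=TRAIN)
        fresh_a = make_word(word_specs[0], token_seed=33)
        agent = Agent(modules=[mod_a, mod_b])
        res = classify(agent, fresh_a, pc=PrecisionConfig.clean_recognition(),
                       settings=FAST)
        assert res.predicted == "a"
        assert res.scores["a"] < res.scores["b"]

    def test_retraining_on_same_token_does_not_increase_error(self, word_specs):
        from shcspeech.inference import learn_feedback

        z = make_word(word_specs[2], token_seed=41)
        mod = train_module("w", [z], settings=TRAIN)
        rec = learn_feedback(mod.model, PrecisionConfig.learning(), z,
                             settings=TRAIN)
        assert rec.error_curve[-1] <= rec.error_curve[0] * 1.01

    def test_empty_stimuli_rejected(self):
        with pytest.raises(ValueError):
            train_module("x", [])


class TestAverageModules:
    def test_single_module_identity(self, small_agent):
        mod = small_agent.modules[0]
        avg = average_modules([mod])
        assert np.allclose(avg.model.fb.I, mod.model.fb.I)
        assert avg.label == mod.label

    def test_copies_average_to_same_weights(self, small_agent):
        mod = small_agent.modules[1]
        avg = average_modules([mod, mod, mod])
        assert np.allclose(avg.model.fb.I, mod.model.fb.I)

    def test_elementwise_mean(self, small_agent):
        a, b = small_agent.modules[0], small_agent.modules[1]
        b_same = WordModule(
            label=a.label, model=b.model, precisions=b.precisions, trained=True
        )
        avg = average_modules([a, b_same])
        assert np.allclose(
            avg.model.fb.I, (a.model.fb.I + b_same.model.fb.I) / 2
        )

    def test_mixed_labels_rejected(self, small_agent):
        with pytest.raises(ValueError, match="label"):
            average_modules(small_agent.modules[:2])


class TestClassify:
    def test_single_module_agent_always_wins_margin_zero(self, small_agent, word_specs):
        solo = Agent(modules=[small_agent.modules[0]])
        z = make_word(word_specs[3], token_seed=55)
        res = classify(solo, z, pc=PrecisionConfig.clean_recognition(), settings=FAST)
        assert res.predicted == small_agent.modules[0].label
        assert res.margin == 0.0

    def test_scores_permutation_equivariant(self, small_agent, word_specs):
        z = make_word(word_specs[0], token_seed=56)
        pc = PrecisionConfig.clean_recognition()
        res_fwd = classify(small_agent, z, pc=pc, settings=FAST)
        rev = Agent(modules=list(reversed(small_agent.modules)))
        res_rev = classify(rev, z, pc=pc, settings=FAST)
        assert res_fwd.predicted == res_rev.predicted
        for k in res_fwd.scores:
            assert res_fwd.scores[k] == pytest.approx(res_rev.scores[k])

    def test_margin_nonnegative(self, small_agent, word_specs):
        z = make_word(word_specs[1], token_seed=57)
        res = classify(small_agent, z, pc=PrecisionConfig.clean_recognition(),
                       settings=FAST)
        assert res.margin >= 0

    def test_empty_agent_rejected(self, word_specs):
        with pytest.raises(ValueError):
            classify(Agent(modules=[]), make_word(word_specs[0], token_seed=1))


class TestScoreSeparability:
    def test_matched_score_lower_in_most_trials(self, word_specs):
        """Matched vs mismatched module pairs on clean tokens: the
        matched score must be strictly lower in >= 95% of trials."""
        mods = [
            train_module(
                word_specs[i].label,
                [make_word(word_specs[i], token_seed=60 + i)],
                settings=TRAIN,
            )
            for i in range(5)
        ]
        pc = PrecisionConfig.clean_recognition()
        from shcspeech.inference import error_summary, infer_states

        wins = trials = 0
        for i in range(5):
            for rep in range(2):
                z = make_word(word_specs[i], token_seed=80 + 10 * i + rep)
                s_match = error_summary(
                    infer_states(mods[i].model, pc, z, settings=FAST)
                )["score"]
                j = (i + 1) % 5
                s_mis = error_summary(
                    infer_states(mods[j].model, pc, z, settings=FAST)
                )["score"]
                trials += 1
                wins += s_match < s_mis
        assert wins / trials >= 0.95


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def tiny_dataset(self):
        ds = DatasetSpec(
            n_classes=4, n_speakers=2, tokens_per_speaker=2, master_seed=3
        )
        tokens, _ = make_dataset(ds)
        return tokens

    def test_clean_wer_zero_on_heldout(self, tiny_dataset):
        res = cross_validate(
            tiny_dataset, {"n_train": 1, "n_test": 1}, seed=0, settings=FAST
        )
        assert res["wer"] <= 0.125  # at most 1 of 8 held-out tokens wrong
        assert res["n_test"] == 8

    def test_training_tokens_reclassified_perfectly(self, tiny_dataset):
        """An agent queried on its own training tokens makes no errors."""
        res = cross_validate(
            tiny_dataset, {"n_train": 1, "n_test": 1}, seed=0, settings=FAST
        )
        agent = res["agent"]
        train_labels = set(agent.labels)
        errs = 0
        for tok in tiny_dataset[:8]:
            if tok.label in train_labels:
                r = classify(agent, tok.stimulus,
                             pc=PrecisionConfig.clean_recognition(), settings=FAST)
                errs += r.predicted != tok.label
        assert errs <= 1

    def test_insufficient_tokens_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="need"):
            cross_validate(tiny_dataset, {"n_train": 2, "n_test": 1}, seed=0)

    def test_label_shuffle_is_at_chance(self, tiny_dataset):
        """Scores ignore the true labels, so shuffling test labels drops
        accuracy to ~chance."""
        rng = np.random.default_rng(0)
        res = cross_validate(
            tiny_dataset, {"n_train": 1, "n_test": 1}, seed=0, settings=FAST
        )
        preds = [r["predicted"] for r in res["records"]]
        true = [r["label"] for r in res["records"]]
        shuffled = rng.permutation(true)
        acc = np.mean([p == s for p, s in zip(preds, shuffled)])
        assert acc <= 0.75  # chance is 0.25 for 4 classes


class TestSerialization:
    def test_agent_json_roundtrip(self, small_agent, tmp_path, word_specs):
        path = tmp_path / "agent.json"
        small_agent.save_json(path)
        back = Agent.load_json(path)
        assert back.labels == small_agent.labels
        z = make_word(word_specs[0], token_seed=99)
        pc = PrecisionConfig.clean_recognition()
        r1 = classify(small_agent, z, pc=pc, settings=FAST)
        r2 = classify(back, z, pc=pc, settings=FAST)
        assert r1.predicted == r2.predicted
        assert r1.scores == pytest.approx(r2.scores)

    def test_duplicate_labels_rejected(self, small_agent):
        with pytest.raises(ValueError):
            Agent(modules=[small_agent.modules[0], small_agent.modules[0]])
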