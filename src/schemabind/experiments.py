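"""Reproducible experiment builders at desk scale.

Each function runs one complete study — data generation, training,
evaluation — from a single integer seed and returns plain dictionaries
of results. These are the configurations exercised by the test suite and
the acceptance script; full-scale runs (5,000 stories per path, 1,000
violation fillers) use the same code paths through `training` and
`probes` with larger numbers.
"""

from __future__ import annotations

import numpy as np

from .decoding import build_decoding_set, decoding_curve, fit_decoders
from .embeddings import Lexicon, build_corpus, corpus_from_lexicon, ranking_score
from .model import RecurrentFillerBinder
from .probes import (RetentionDesign, ViolationDesign, ambiguous_probe,
                     build_retention_datasets, build_violation_datasets,
                     residual_bias, run_violation_eval)
from .training import ExperimentSpec, build_limited_datasets, \
    build_unlimited_datasets, evaluate

#: desk-scale condition for the limited/disjoint-filler experiment:
#: 2 schema paths, 200 stories per path, 6 fillers per role
LIMITED_UNSEEN_SCALE = dict(n_paths=2, stories_per_path=200,
                            test_stories_per_path=50)

#: desk-scale violation design: 100 fillers, per-role pools of 75/25
VIOLATION_SCALE = dict(universe=100, n_train=2000, n_test=200)


def run_limited_unseen_lstm(seed: int, max_epochs: int = 600) -> dict:
    """Train an LSTM on a small filler pool; test on a disjoint pool.

    The network is trained (Adam, lr 1e-4, MSE) until training-set
    retrieval accuracy exceeds 90%, then evaluated on stories whose
    fillers it has never seen. Returns train/test accuracy and the
    fraction of test predictions that are training-pool fillers.
    """
    rng = np.random.default_rng(seed)
    spec = ExperimentSpec(regime="limited_unseen", seed=seed,
                          **LIMITED_UNSEEN_SCALE)
    train, test, lexicon = build_limited_datasets(spec, rng)
    model = RecurrentFillerBinder(
        architecture="lstm", learning_rate=1e-4, max_epochs=max_epochs,
        stop_accuracy=0.95, patience=10 ** 9, eval_every=5, random_state=seed)
    model.fit(train, lexicon)
    corpus = corpus_from_lexicon(lexicon)
    train_pool = {t for s in train for t in s.binding.values()}
    train_vocab = {t for s in train for t in s.tokens} | train_pool
    predictions = model.predict(test, lexicon, corpus)
    return {
        "model": model, "lexicon": lexicon, "corpus": corpus,
        "train": train, "test": test,
        "train_accuracy": model.score(train, lexicon, corpus),
        "test_accuracy": model.score(test, lexicon, corpus),
        "predictions": predictions,
        "frac_predictions_in_train_pool":
            float(np.mean([p in train_pool for p in predictions])),
        "frac_predictions_in_train_vocab":
            float(np.mean([p in train_vocab for p in predictions])),
        "chance": corpus.chance_rate,
    }


def run_violation_fastweights(seed: int, max_epochs: int = 250,
                              learning_rate: float = 1e-2,
                              settle_steps: int = 1) -> dict:
    """Fast Weights on the reduced correlation-violation design.

    Trains to convergence on correlation-respecting bindings and reports
    accuracy on the test set in which every varied role is bound only to
    the fillers excluded from it during training.
    """
    rng = np.random.default_rng(seed)
    design = ViolationDesign(**VIOLATION_SCALE)
    train, test, lexicon = build_violation_datasets(design, rng)
    model = RecurrentFillerBinder(
        architecture="fastweights", learning_rate=learning_rate,
        settle_steps=settle_steps, max_epochs=max_epochs, stop_accuracy=1.0,
        patience=10 ** 9, eval_every=5, random_state=seed)
    model.fit(train, lexicon)
    result = run_violation_eval(model, test, lexicon)
    result.update(model=model, lexicon=lexicon, design=design,
                  train=train, test=test,
                  train_accuracy=model.score(
                      train[:400], lexicon, corpus_from_lexicon(lexicon)))
    return result


def ranking_chance(seed: int, n_draws: int = 10_000, corpus_size: int = 126) -> dict:
    """Mean ranking score of random, uninformative prediction vectors."""
    rng = np.random.default_rng(seed)
    lexicon = Lexicon.build([f"w{i}" for i in range(corpus_size)], rng)
    corpus = corpus_from_lexicon(lexicon)
    scores = [
        ranking_score(rng.standard_normal(50),
                      f"w{int(rng.integers(corpus_size))}", corpus)
        for _ in range(n_draws)
    ]
    return {"mean_score": float(np.mean(scores)), "n": n_draws}


def run_unlimited(architecture: str, seed: int, max_epochs: int = 1600,
                  learning_rate: float = 1e-2, n_test_draws: int = 6) -> dict:
    """Unlimited-filler regime over all 112 frames with fresh fillers.

    Returns overall and per-query accuracy on freshly drawn test
    stories, with the per-batch corpus chance rate.
    """
    rng = np.random.default_rng(seed)
    spec = ExperimentSpec(regime="unlimited", seed=seed)
    frames, resample, val, lexicon = build_unlimited_datasets(spec, rng)
    model = RecurrentFillerBinder(
        architecture=architecture, learning_rate=learning_rate,
        max_epochs=max_epochs, patience=10 ** 9, eval_every=10 ** 9,
        random_state=seed)
    model.fit([], lexicon, validation=val, resample=resample)
    test = []
    for _ in range(n_test_draws):
        test.extend(resample(rng))
    report = evaluate(model, test, lexicon)
    return {"model": model, "lexicon": lexicon, "resample": resample,
            "report": report}


def decoding_comparison(model: RecurrentFillerBinder, lexicon, seed: int,
                        n_sequences: int = 100) -> dict:
    """External-memory vs hidden-state decodability at query time.

    Fits the per-(role, timestep, component) ridge bank on the
    full-coverage frame and returns the final-timestep (query-time) mean
    ranking score per role and component.
    """
    rng = np.random.default_rng(seed)
    dset = build_decoding_set(model, lexicon, rng, n_sequences=n_sequences)
    bank = fit_decoders(dset)
    curve = decoding_curve(bank, dset, corpus_from_lexicon(lexicon))
    last = curve[curve.timestep == curve.timestep.max()]
    out = {}
    for _, row in last.iterrows():
        out[(row["role"], row["component"])] = row["score"]
    return {"query_time_scores": out, "curve": curve}


def run_retention_fastweights(seed: int, max_epochs: int = 200,
                              learning_rate: float = 2e-2,
                              n_train: int = 256, n_test: int = 240) -> dict:
    """One correlation-retention trial with the Fast Weights network.

    Trains on the linear frame with role-correlated filler distributions
    (X for Dessert/Emcee/Poet, Y for Subject/Friend/Drink) and runs the
    ambiguous zero-vector probe and the all-Z residual-bias probe.
    """
    rng = np.random.default_rng(seed)
    design = RetentionDesign(n_train=n_train, n_test=n_test)
    resample, tests, lexicon = build_retention_datasets(design, rng)
    model = RecurrentFillerBinder(
        architecture="fastweights", learning_rate=learning_rate,
        max_epochs=max_epochs, patience=10 ** 9, eval_every=10 ** 9,
        random_state=seed)
    model.fit([], lexicon, validation=tests["mixed-XY"], resample=resample)
    ambiguous = ambiguous_probe(model, tests["mixed-XY"], lexicon)
    residual = residual_bias(model, tests["all-Z"], lexicon)
    return {"model": model, "lexicon": lexicon, "tests": tests,
            "ambiguous": ambiguous, "residual": residual}
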