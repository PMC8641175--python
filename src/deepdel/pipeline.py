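"""End-to-end synthetic pipeline: simulate -> extract -> train -> call -> evaluate.

This is the driver behind the ``end2end`` CLI subcommand and the
reproducibility script.  All randomness (simulation, weight
initialisation, epoch shuffling) flows from one root seed.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

from .caller import call_deletions, read_vcf_calls, write_vcf
from .config import ModelConfig, SimulationConfig, TrainingConfig
from .evaluate import (MatchCriteria, breakpoint_accuracy, match_calls,
                       window_auc)
from .labels import load_truth
from .nn import WindowClassifier, train
from .nn.train import evaluate_loss_and_scores
from .simulate import make_dataset


def derive_seed(root: int, k: int) -> int:
    """Deterministic per-component seed below 2**31."""
    return (root * 100003 + k * 10007 + 17) % (2 ** 31)


def easy_fixture_configs(seed: int) -> tuple[SimulationConfig, ...]:
    """The 'easy regime' benchmark: three disjoint 1 Mb genomes with 20
    implanted deletions of 50–2000 bp each, 30x coverage, noise rate 5e-4."""
    base = dict(genome_length=1_000_000, n_deletions=20,
                deletion_size_range=(50, 2000), coverage=30.0,
                noise_deletion_rate=5e-4)
    return tuple(SimulationConfig(seed=derive_seed(seed, k), **base)
                 for k in (1, 2, 3))


def run_end2end(seed: int, out_dir: str | Path,
                sim_configs: tuple[SimulationConfig, ...] | None = None,
                model_config: ModelConfig | None = None,
                training_config: TrainingConfig | None = None,
                verbose: bool = False) -> dict:
    """Full synthetic loop; returns a metrics dict (also written as JSON)."""
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_train, cfg_val, cfg_test = sim_configs or easy_fixture_configs(seed)
    model_config = model_config or ModelConfig()
    training_config = training_config or TrainingConfig(
        shuffle_seed=derive_seed(seed, 4), max_epochs=40)

    data = make_dataset(cfg_train, cfg_val, cfg_test, out_dir,
                        n=model_config.n, T=model_config.T)

    model = WindowClassifier(model_config, seed=derive_seed(seed, 5))
    history = train(model, data["train"]["batches"], data["val"]["batches"],
                    training_config, verbose=verbose)
    model.save(out_dir / "model")

    _, val_scores, val_labels = evaluate_loss_and_scores(
        model, data["val"]["batches"], training_config.loss_a)
    val_auc = window_auc(val_scores, val_labels)

    # call deletions on the held-out test genome
    test = data["test"]
    scored = model.predict_windows(test["batches"])
    calls = call_deletions(scored, str(test["bam"]))
    vcf_path = write_vcf(calls, {cfg_test.contig: cfg_test.genome_length},
                         out_dir / "calls.vcf")
    reported = read_vcf_calls(vcf_path)
    truths = load_truth(test["vcf"], min_size=50)
    report = match_calls(reported, truths, MatchCriteria())
    bp_acc = breakpoint_accuracy(reported, truths, report)

    _, test_scores, test_labels = evaluate_loss_and_scores(
        model, test["batches"], training_config.loss_a)
    test_auc = window_auc(test_scores, test_labels)

    metrics = {
        "seed": seed,
        "validation_auc": val_auc,
        "test_auc": test_auc,
        "precision": report.precision,
        "recall": report.recall,
        "f1": report.f1,
        "tp": report.tp, "fp": report.fp, "fn": report.fn,
        "n_truth_deletions": len(truths),
        "n_calls": len(reported),
        "breakpoint_within_40bp": bp_acc["start_within"],
        "size_within_10pct": bp_acc["size_within"],
        "both_within": bp_acc["both_within"],
        "epochs_trained": len(history["epoch"]),
        "best_epoch": history["best_epoch"],
        "final_train_loss": history["train_loss"][-1],
        "runtime_seconds": time.time() - t0,
    }
    (out_dir / "end2end_report.json").write_text(json.dumps(metrics, indent=1))
    return metrics
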