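"""End-to-end study workflows composed from the library modules.

Two workflows used by the CLI, the test suite and the acceptance script:

* :func:`run_three_tier` — pretrain on a large synthetic tier, fine-tune on a
  mid-size transfer tier, and few-shot predict on a small tier, reporting
  weighted recall on held-out queries of each tier.
* :func:`run_single_label_ablation` — train once on multi-label data and once
  on its single-label-filtered version, evaluating both against the same
  multi-label truth.

Desk-scale defaults (head widths, pair counts, epoch budgets) are chosen so
a full three-seed study runs in minutes on one CPU; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem_io import InteractionDataset
from .evaluation import evaluate_predictions
from .inference import build_support_set, few_shot_predict, predict_targets, truth_matrix
from .pair_sampler import filter_single_label, generate_pairs, split_dataset
from .snn_core import SiameseModel, TrainConfig, fine_tune, train
from .synth_data import ScenarioSpec, generate_fewshot_scenario


@dataclass
class PipelineConfig:
    """Budgets for the desk-scale synthetic studies."""

    hidden_dims: tuple = (512, 512, 512)
    dropout_rate: float = 0.5
    pretrain_pairs: int = 2000  # per class
    transfer_pairs: int = 1000  # per class
    val_pairs: int = 400  # per class
    train_cfg: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            learning_rate=1e-4, batch_size=128, max_epochs=6, patience=2
        )
    )
    support_cap: int = 100
    threshold: float = 0.5
    weights: str = "support"


def _train_phase(model, ds_split, n_pairs, n_val, cfg: PipelineConfig, seed, phase):
    tr = generate_pairs(ds_split.train, n_pairs, n_pairs, seed=seed)
    val = generate_pairs(ds_split.validation, n_val, n_val, seed=seed + 1)
    tc = TrainConfig(**{**cfg.train_cfg.__dict__, "seed": seed})
    if phase == "transfer":
        fine_tune(model, tr, val, tc)
    else:
        train(model, tr, val, tc, phase=phase)
    return model


def _tier_recall(model, split, cfg: PipelineConfig, seed) -> tuple[float, int]:
    support = build_support_set(split.train, cap=cfg.support_cap, seed=seed)
    queries = [split.test.compounds[c] for c in split.test.compound_ids]
    pred = predict_targets(model, support, queries, threshold=cfg.threshold)
    truth = truth_matrix(split.test, pred.query_ids, pred.protein_ids)
    rec = evaluate_predictions(pred, truth, weights=cfg.weights).weighted["recall"]
    return rec, len(queries)


def run_three_tier(
    seed: int = 0,
    scenario: ScenarioSpec | None = None,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Pretrain -> transfer -> few-shot on the three-tier synthetic scenario.

    Returns a dict with the trained model and held-out weighted recall per
    tier: the base tier is evaluated with the pretrained model, the transfer
    tier with the fine-tuned model, and the few-shot tier by support/query
    splitting with no further weight updates.
    """
    cfg = cfg or PipelineConfig()
    base, transfer, fewshot = generate_fewshot_scenario(seed=seed, scenario=scenario)

    base_split = split_dataset(base, seed=seed)
    model = SiameseModel.create(
        base.fingerprint_spec, hidden_dims=cfg.hidden_dims,
        dropout_rate=cfg.dropout_rate, seed=seed,
    )
    _train_phase(model, base_split, cfg.pretrain_pairs, cfg.val_pairs, cfg, seed, "train")
    recall_base, n_base = _tier_recall(model, base_split, cfg, seed)

    transfer_split = split_dataset(transfer, seed=seed)
    _train_phase(model, transfer_split, cfg.transfer_pairs, cfg.val_pairs, cfg,
                 seed + 10, "transfer")
    recall_transfer, n_transfer = _tier_recall(model, transfer_split, cfg, seed)

    pred, truth = few_shot_predict(model, fewshot, threshold=cfg.threshold, seed=seed)
    recall_fewshot = evaluate_predictions(pred, truth, weights=cfg.weights).weighted["recall"]

    return {
        "model": model,
        "recall_base": recall_base,
        "recall_transfer": recall_transfer,
        "recall_fewshot": recall_fewshot,
        "n_queries": {
            "base": n_base, "transfer": n_transfer, "fewshot": len(pred.query_ids),
        },
    }


def default_ablation_spec(seed: int = 0) -> "SynthSpec":
    """Multi-label synthetic conditions for the single-label ablation study:
    a third of actives carry a second target protein."""
    from .synth_data import SynthSpec

    return SynthSpec(
        n_proteins=4, actives_per_protein=300, inactives_per_protein=150,
        multi_label_rate=0.3, protein_prefix="ML", seed=seed,
    )


def run_single_label_ablation(
    ds: InteractionDataset,
    seed: int = 0,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Train on multi-label data vs its single-label filtering; evaluate both
    against the same multi-label test truth.

    Returns weighted recalls of the two models and their absolute gap.
    """
    cfg = cfg or PipelineConfig()
    split = split_dataset(ds, seed=seed)
    single_train = filter_single_label(split.train, seed=seed)

    recalls = {}
    for tag, train_ds in (("multi", split.train), ("single", single_train)):
        tmp_split = split_dataset(ds, seed=seed)  # identical partition
        model = SiameseModel.create(
            ds.fingerprint_spec, hidden_dims=cfg.hidden_dims,
            dropout_rate=cfg.dropout_rate, seed=seed,
        )
        tr = generate_pairs(train_ds, cfg.transfer_pairs, cfg.transfer_pairs, seed=seed)
        val = generate_pairs(tmp_split.validation, cfg.val_pairs, cfg.val_pairs, seed=seed + 1)
        tc = TrainConfig(**{**cfg.train_cfg.__dict__, "seed": seed})
        train(model, tr, val, tc, phase=f"train-{tag}")
        support = build_support_set(train_ds, cap=cfg.support_cap, seed=seed)
        queries = [split.test.compounds[c] for c in split.test.compound_ids]
        pred = predict_targets(model, support, queries, threshold=cfg.threshold)
        truth = truth_matrix(split.test, pred.query_ids, pred.protein_ids)
        recalls[tag] = evaluate_predictions(pred, truth, weights=cfg.weights).weighted["recall"]

    return {
        "recall_multi": recalls["multi"],
        "recall_single": recalls["single"],
        "gap": abs(recalls["multi"] - recalls["single"]),
        "n_queries": len(split.test),
    }
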