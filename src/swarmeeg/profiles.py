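"""Built-in run profiles.

``paper``: the full-scale configuration (9000-unit bottleneck, 4500
selected features, DNN hidden layers 2250/500, LSTM state 250) — sized
for the real datasets and hours of compute.

``test``: all widths shrunk roughly 30x so a full cross-validated run
completes in minutes; the algorithms and schedules are unchanged.
"""

from __future__ import annotations

import copy

PROFILES: dict[str, dict] = {
    "paper": {
        "sasdl": {
            "sae_params": {"bottleneck": 9000, "weight_decay": 0.01,
                           "sparse_penalty": 4.0, "sparsity_target": 0.08,
                           "iterations": 50, "batch_size": 10},
            "selector_params": {"n_selected": 4500},
            "dnn_params": {"hidden_sizes": (2250, 500), "dropout": 0.5,
                           "epochs": 50, "fine_tune_epochs": 20,
                           "batch_size": 10},
        },
        "rbatq": {"state_size": 250, "hidden": 100, "dropout": 0.75,
                  "learning_rate": 0.002, "batch_size": 25, "max_norm": 3.0,
                  "pretrain_epochs": 20, "q_epochs": 20},
        "data": {"n_recordings_per_class": 100},
    },
    "test": {
        "sasdl": {
            "sae_params": {"layer_sizes": (178, 256, 178),
                           "weight_decay": 0.01, "sparse_penalty": 4.0,
                           "sparsity_target": 0.08, "iterations": 100,
                           "batch_size": 10, "learning_rate": 1e-3},
            "selector_params": {"n_selected": 128, "generations": 6,
                                "population": 8, "fitness_epochs": 6,
                                "fitness_hidden": (16,),
                                "fitness_learning_rate": 0.02,
                                "fitness_scoring": "soft"},
            "dnn_params": {"hidden_sizes": (64, 16), "dropout": 0.1,
                           "epochs": 50, "fine_tune_epochs": 20,
                           "batch_size": 10, "learning_rate": 0.01},
        },
        "rbatq": {"state_size": 16, "hidden": 32, "frame_width": 11,
                  "dropout": 0.1, "learning_rate": 0.002, "batch_size": 25,
                  "max_norm": 3.0, "pretrain_epochs": 12, "q_epochs": 8},
        "data": {"n_recordings_per_class": 20},
    },
}


def get_profile(name: str) -> dict:
    if name not in PROFILES:
        raise KeyError(f"unknown profile {name!r}; choose from "
                       f"{sorted(PROFILES)}")
    return copy.deepcopy(PROFILES[name])
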