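"""Learn the regulatory-network ensemble.

Each network models every gene's expression from its own copy number and
all non-local genes' expression (|genome-index gap| > 50), selecting
predictors along the lasso path with the covariance significance test at
q <= 0.01 on two-thirds of the tumors per random split.
"""
import sys
from pathlib import Path

from oligonet.pipeline import run_pipeline

CONFIG = Path(__file__).resolve().parents[1] / "configs" / "scaled_default.yaml"


def main() -> None:
    state, out = run_pipeline(CONFIG, stages=("simulate", "preprocess", "infer"))
    for j, net in enumerate(state.ensemble):
        print(f"network {j}: {len(net.train_ids)} train / {len(net.test_ids)} test, "
              f"{net.n_edges()} edges, {net.activator_fraction():.0%} activators")
    print(f"edge lists under {out}")


if __name__ == "__main__":
    sys.exit(main())
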