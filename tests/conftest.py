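import numpy as np
import pytest

import perturbcf as pcf


@pytest.fixture(scope="session")
def tiny_screen():
    """Small combinatorial screen with profile outcomes (fast to train on)."""
    cfg = pcf.SynthConfig(
        n_genes=30,
        n_latent_true=5,
        n_perturbations=4,
        n_pairs=3,
        n_cells_per_condition=15,
        seed=0,
    )
    screen, truth = pcf.simulate_screen(cfg)
    return screen, truth


@pytest.fixture(scope="session")
def tiny_model(tiny_screen):
    screen, _ = tiny_screen
    cfg = pcf.ModelConfig(
        input_dim=screen.controls.n_genes,
        output_dim=screen.controls.n_genes,
        latent_dim=6,
        encoder_widths=[12],
        decoder_widths=[12],
        seed=0,
    )
    return pcf.BranchedModel(cfg, screen.design.perturbation_ids)


@pytest.fixture
def csv_trio(tmp_path):
    """Write a 3-sample screen as CSV files; returns the three paths."""

    def _write(sample_ids=("s1", "s2", "s3"), bad_control=None):
        rng = np.random.default_rng(7)
        genes = ["gA", "gB", "gC", "gD"]
        expr = pcf.ExpressionMatrix(rng.random((3, 4)), genes, list(sample_ids))
        expr.to_frame().to_csv(tmp_path / "expr.csv")
        controls = list(sample_ids) if bad_control is None else [bad_control] * 3
        import pandas as pd

        design = pd.DataFrame(
            {"control": controls, "p1": [1, 0, 1], "p2": [0, 1, 1]},
            index=["e1", "e2", "e3"],
        )
        design.to_csv(tmp_path / "design.csv")
        pd.DataFrame({"outcome": [0.1, 0.5, -0.3]}, index=["e1", "e2", "e3"]).to_csv(
            tmp_path / "outcome.csv"
        )
        return tmp_path / "expr.csv", tmp_path / "design.csv", tmp_path / "outcome.csv"

    return _write
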