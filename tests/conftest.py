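import numpy as np
import pandas as pd
import pytest

import panelgwas as pg


@pytest.fixture(scope="session")
def small_config():
    """A fast panel: 60 lines, 5 batches with controls in 4, 300 markers."""
    return pg.SimConfig(
        n_lines=60,
        n_variants=300,
        n_batches=5,
        lines_per_batch=(8, 14),
        control_batch_coverage=4,
        brains_per_line=(8, 14),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_geno(small_config):
    return pg.simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_panel(small_config, small_geno):
    panel, truth = pg.simulate_phenotypes(small_geno, small_config)
    return panel, truth


@pytest.fixture()
def toy_tgeno(tmp_path):
    """3 variants x 4 lines with one missing call on the first variant."""
    text = (
        "chr pos id ref alt RAL-1 RAL-2 RAL-3 RAL-4\n"
        "3R 10296407 3R_10296407_SNP A G 0 2 - 2\n"
        "2L 500 2L_500_SNP C T 0 0 2 2\n"
        "X 900 X_900_DEL CA C 2 2 0 0\n"
    )
    path = tmp_path / "toy.tgeno"
    path.write_text(text)
    return path


@pytest.fixture()
def toy_panel():
    """Three batches, two control lines with deliberately unequal brain
    numbers, plus one test line per batch."""
    rows = []

    def add(line, batch, counts):
        rows.extend((line, batch, c) for c in counts)

    add("CTRL-A", "b1", [20, 22])
    add("CTRL-B", "b1", [28, 30, 32])
    add("CTRL-A", "b2", [24, 26, 28, 30])
    add("CTRL-B", "b2", [30])
    add("CTRL-A", "b3", [18])
    add("CTRL-B", "b3", [26, 28])
    add("T-1", "b1", [25, 27])
    add("T-2", "b2", [31, 29, 33])
    add("T-3", "b3", [22, 24])
    counts = pd.DataFrame(rows, columns=["line_id", "batch_id", "count"])
    lines = pd.DataFrame(
        {
            "is_control": {
                "CTRL-A": True, "CTRL-B": True,
                "T-1": False, "T-2": False, "T-3": False,
            }
        }
    )
    lines.index.name = "line_id"
    return pg.PhenotypePanel(lines=lines, counts=counts)
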