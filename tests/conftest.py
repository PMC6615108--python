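"""Shared fixtures: small hand-built plates and one full synthetic run."""

import numpy as np
import pandas as pd
import pytest

from qplexflow import AnnotatedPlate, make_truth, run_plate, simulate_plate
from qplexflow.plate_io import ROLE_BACKGROUND, ROLE_NEGATIVE, ROLE_SAMPLE


def build_plate(annotations: dict, mfi: dict, bead_counts=None, hkg=("HKG1",), title="test"):
    """Assemble an AnnotatedPlate from plain dicts.

    ``annotations``: well -> (role, compound, concentration);
    ``mfi``: gene -> {well: value}; bead_counts analogous (default 60).
    """
    ann = pd.DataFrame(
        [
            {"well_id": w, "role": r, "compound": c, "concentration": x,
             "cell_count": 2500, "timepoint": "24h", "cell_line": "L"}
            for w, (r, c, x) in annotations.items()
        ]
    ).set_index("well_id")
    mfi_df = pd.DataFrame(mfi, dtype=float).reindex(ann.index)
    if bead_counts is None:
        beads = pd.DataFrame(60, index=mfi_df.index, columns=mfi_df.columns)
    else:
        beads = pd.DataFrame(bead_counts).reindex(ann.index).fillna(60).astype(int)
    return AnnotatedPlate(
        title=title, annotations=ann, mfi=mfi_df, bead_counts=beads, hkg_names=list(hkg)
    )


@pytest.fixture(scope="session")
def screening_sim(tmp_path_factory):
    """One noisy screening-plate simulation with files on disk."""
    out = tmp_path_factory.mktemp("sim")
    truth = make_truth(seed=11, noise_sd=0.05)
    return simulate_plate(truth, out_dir=out)


@pytest.fixture(scope="session")
def screening_run(screening_sim):
    """Full pipeline result on the screening plate (computed once per session)."""
    return run_plate(screening_sim.plate.copy())


ROLES = {"background": ROLE_BACKGROUND, "negative": ROLE_NEGATIVE, "sample": ROLE_SAMPLE}
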