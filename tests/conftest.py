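import pandas as pd
import pytest

from rlddm import models, task


@pytest.fixture(scope="session")
def schedule60():
    return task.generate_task_schedule(seed=0)


@pytest.fixture(scope="session")
def rlddm8_spec():
    return models.get_model("RLDDM8")


@pytest.fixture(scope="session")
def control_dataset(schedule60, rlddm8_spec):
    """12 simulated control subjects with their generating parameters."""
    gp = task.group_presets("control")
    data, truth = task.simulate_group(gp, 12, rlddm8_spec, schedule60, seed=11, group="control")
    return data, truth


@pytest.fixture(scope="session")
def control_filtered(control_dataset):
    return models.preprocess_rts(control_dataset[0])


def make_subject_df(signed_rts, pair=0, trial_start=1, participant_id="s01", group="control"):
    """Build a minimal preprocessed single-subject frame from signed RTs."""
    n = len(signed_rts)
    rows = []
    for i, x in enumerate(signed_rts):
        rows.append({
            "participant_id": participant_id,
            "group": group,
            "trial": trial_start + i,
            "pair": pair,
            "choice": "optimal" if x > 0 else "suboptimal",
            "rt": abs(x),
            "reward": 1,
        })
    return models.preprocess_rts(pd.DataFrame(rows))
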