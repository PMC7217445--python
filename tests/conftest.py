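import numpy as np
import pandas as pd
import pytest

import ovichoice as oc
from ovichoice import tables
from ovichoice.data import ChoiceDataset
from ovichoice.design import Attribute, assign_blocks, full_factorial


def make_binary_dataset(n, beta, seed):
    """2 alternatives, 1 attribute with codes (+1, -1): the MLE without ASCs
    has the closed form beta_hat = logit(share choosing +1) / 2."""
    rng = np.random.default_rng(seed)
    u = np.array([beta, -beta])
    p = np.exp(u) / np.exp(u).sum()
    choice = rng.random(n) < p[0]
    rows = []
    for i, c in enumerate(choice, start=1):
        rows.append((i, 1, 1, int(c), 0, 1))
        rows.append((i, 1, 2, int(not c), 0, -1))
    df = pd.DataFrame(
        rows,
        columns=["respondent_id", "situation_id", "alternative_id", "chosen", "is_opt_out", "z"],
    )
    return ChoiceDataset([Attribute("z")], df), choice.mean()


@pytest.fixture(scope="session")
def ram_plan():
    return oc.study_design("ram", seed=0)


@pytest.fixture(scope="session")
def ewe_plan():
    return oc.study_design("ewe", seed=0)


@pytest.fixture(scope="session")
def toy_plan():
    """Four generic attributes, full factorial in 4 blocks of 4: both the
    full and any one-alternative-restricted conditional logit are identified."""
    attrs = [Attribute(f"x{j}") for j in (1, 2, 3, 4)]
    return assign_blocks(full_factorial(attrs), 4, seed=3, attributes=attrs)


@pytest.fixture(scope="session")
def toy_truth():
    return oc.TruePreferences(
        beta={"x1": 0.5, "x2": -0.3, "x3": 0.2, "x4": 0.4},
        asc=[0, 0.2, -0.1, 0.3],
    )


@pytest.fixture(scope="session")
def ram_dataset(ram_plan):
    truth = oc.preset_truth("ram")
    return oc.simulate_choices(ram_plan, truth, tables.N_RESPONDENTS, seed=1)


@pytest.fixture(scope="session")
def ram_filtered(ram_dataset):
    filtered, _ = oc.drop_opt_outs(ram_dataset)
    return filtered


@pytest.fixture(scope="session")
def toy_dataset(toy_plan, toy_truth):
    return oc.simulate_choices(toy_plan, toy_truth, 400, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
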