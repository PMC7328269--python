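import shutil
import subprocess
from pathlib import Path

import numpy as np
import pytest

from methbatch import (
    assign_groups,
    build_layout,
    emulate_parameter_profile,
    generate_null_betas,
)

ORACLE_DIR = Path(__file__).parent / "oracles"


@pytest.fixture(scope="session")
def small_profile():
    return emulate_parameter_profile(2000, seed=11)


@pytest.fixture(scope="session")
def layout48_random():
    return assign_groups(build_layout(48), "random", seed=5)


@pytest.fixture(scope="session")
def layout48_unbalanced():
    return assign_groups(build_layout(48), "unbalanced")


@pytest.fixture(scope="session")
def layout48_balanced():
    return assign_groups(build_layout(48), "balanced")


@pytest.fixture()
def null_betas(small_profile, layout48_random):
    return generate_null_betas(small_profile, layout48_random, seed=21)


def run_r_oracle(script: str, *args: str) -> None:
    """Run one of the R reference scripts under tests/oracles/."""
    rscript = shutil.which("Rscript")
    assert rscript is not None, "Rscript is required for reference-oracle tests"
    proc = subprocess.run(
        [rscript, str(ORACLE_DIR / script), *map(str, args)],
        capture_output=True,
        text=True,
    )
    assert proc.returncode == 0, f"R oracle failed:\n{proc.stderr}"


@pytest.fixture(scope="session")
def r_oracle():
    return run_r_oracle


def save_matrix(path, mat) -> np.ndarray:
    """Write a matrix for an R oracle and return exactly what R will read."""
    np.savetxt(path, mat, delimiter=",", fmt="%.17g")
    return np.loadtxt(path, delimiter=",")
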