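"""Shared fixtures: hand-built pedigrees and cached simulation runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from telodyn import Pedigree, compute_kinship

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def make_pedigree(rows) -> Pedigree:
    """Build a pedigree from (id, sire, dam, sex, age) tuples."""
    t = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "age"])
    return Pedigree(t)


@pytest.fixture(scope="session")
def trio():
    """Sire, dam and one offspring."""
    return make_pedigree([
        ("s", None, None, "M", 12.0),
        ("d", None, None, "F", 11.0),
        ("c", "s", "d", "F", 4.0),
    ])


@pytest.fixture(scope="session")
def nuclear_family():
    """Two founders and four full-sib offspring."""
    rows = [("s", None, None, "M", 12.0), ("d", None, None, "F", 11.0)]
    rows += [(f"c{k}", "s", "d", "F" if k % 2 else "M", 4.0)
             for k in range(4)]
    return make_pedigree(rows)


@pytest.fixture(scope="session")
def inbred_line():
    """Full-sib mating: offspring of sibs whose parents are founders."""
    return make_pedigree([
        ("gs", None, None, "M", 20.0),
        ("gd", None, None, "F", 20.0),
        ("b", "gs", "gd", "M", 10.0),
        ("sis", "gs", "gd", "F", 10.0),
        ("x", "b", "sis", "F", 2.0),
    ])


@pytest.fixture(scope="session")
def three_generation():
    """Six-member pedigree spanning three generations with a half-sib."""
    return make_pedigree([
        ("a", None, None, "M", 20.0),
        ("b", None, None, "F", 20.0),
        ("c", None, None, "F", 18.0),
        ("d", "a", "b", "M", 10.0),
        ("e", "a", "c", "F", 9.0),
        ("f", "d", "e", "F", 2.0),
    ])


@pytest.fixture(scope="session")
def random_pedigree_30():
    """Random 30-member, 3-generation pedigree for oracle checks."""
    rng = np.random.default_rng(2024)
    rows = []
    prev = []
    counter = 0
    for gen in range(3):
        members = []
        n_gen = 10
        for _ in range(n_gen):
            counter += 1
            iid = f"i{counter:02d}"
            sex = "F" if rng.random() < 0.5 else "M"
            if gen == 0 or not prev:
                rows.append((iid, None, None, sex, 20.0 - 6 * gen))
            else:
                males = [i for i, s in prev if s == "M"]
                females = [i for i, s in prev if s == "F"]
                if not males or not females:
                    rows.append((iid, None, None, sex, 20.0 - 6 * gen))
                else:
                    sire = males[int(rng.integers(len(males)))]
                    dam = females[int(rng.integers(len(females)))]
                    rows.append((iid, sire, dam, sex, 20.0 - 6 * gen))
            members.append((iid, sex))
        prev = members
    return make_pedigree(rows)


@pytest.fixture(scope="session")
def small_kinships(trio, nuclear_family, inbred_line, three_generation):
    peds = [trio, nuclear_family, inbred_line, three_generation]
    return [(p, compute_kinship(p)) for p in peds]
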