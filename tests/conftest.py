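"""Shared fixtures: small ground-truthed datasets built at test time."""

import numpy as np
import pytest

from hrgcms import simulate
from hrgcms.chem import MONOISOTOPIC_MASS, DecompositionConstraints, Formula
from hrgcms.chem import element_ratio_check, rdbe, senior_check


@pytest.fixture(scope="session")
def truth_and_library():
    """A 30-compound ground truth with an 80% library (seeded)."""
    return simulate.generate_compounds(30, seed=11, library_fraction=0.8)


@pytest.fixture(scope="session")
def twin(truth_and_library):
    """Default-condition twin experiment on the shared compound set."""
    truth, _ = truth_and_library
    return simulate.generate_experiment(truth, seed=12)


def brute_force_decompose(mass, constraints: DecompositionConstraints, as_fragment_ion=False):
    """Independent decomposition oracle: enumerate the full element-count
    lattice with numpy, select compositions inside the ppm window, and
    apply the same plausibility filters as the search (the enumeration —
    the part under test — is independent)."""
    from hrgcms.chem import ELECTRON_MASS

    elements = [el for el, (lo, hi) in constraints.element_ranges.items() if hi > 0 or lo > 0]
    ranges = [constraints.element_ranges[el] for el in elements]
    grids = np.meshgrid(*[np.arange(lo, hi + 1) for lo, hi in ranges], indexing="ij")
    counts = np.stack([g.ravel() for g in grids], axis=1)
    masses = counts @ np.array([MONOISOTOPIC_MASS[el] for el in elements])
    target = mass + ELECTRON_MASS if as_fragment_ion else mass
    tol_da = mass * constraints.tolerance_ppm * 1e-6
    hits = np.nonzero(np.abs(masses - target) <= tol_da)[0]
    found = set()
    for i in hits:
        f = Formula({el: int(c) for el, c in zip(elements, counts[i]) if c > 0})
        if f.is_empty:
            continue
        r = rdbe(f)
        lo, hi = constraints.rdbe_range
        if not (lo <= r <= hi):
            continue
        if not (constraints.allow_half_integer_rdbe or as_fragment_ion) and (2 * r) % 2 != 0:
            continue
        if constraints.senior and not as_fragment_ion and not senior_check(f):
            continue
        if constraints.ratio_check and not element_ratio_check(f, constraints.ratio_ranges):
            continue
        found.add(f)
    return found
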