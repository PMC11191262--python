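import numpy as np
import pytest

from trialfca.preprocessing import Descriptor, DescriptorTable
from trialfca.rule_mining import FormalContext, build_context


def random_context(rng: np.random.Generator, n_subjects=None, n_descriptors=None,
                   density=None, with_missing=False) -> FormalContext:
    """A random formal context over two-category variables.

    Descriptors come in pairs (var=a / var=b) so the mutual-exclusivity
    invariant of real descriptor tables holds; a cell can also be unmeasured
    when ``with_missing`` is set.
    """
    n = int(n_subjects if n_subjects is not None else rng.integers(4, 16))
    n_vars = int((n_descriptors if n_descriptors is not None else rng.integers(4, 13)) // 2)
    n_vars = max(n_vars, 2)
    dens = float(density if density is not None else rng.uniform(0.3, 0.7))
    table = DescriptorTable()
    subjects = [f"s{i:02d}" for i in range(n)]
    table.subject_ids = subjects
    for v in range(n_vars):
        var = f"v{v}"
        for sid in subjects:
            if with_missing and rng.random() < 0.15:
                continue  # unmeasured cell
            category = "a" if rng.random() < dens else "b"
            table.add(sid, var, category, ("a", "b"))
        if var not in table.measured:  # every column fully unmeasured: re-add one
            table.add(subjects[0], var, "a", ("a", "b"))
    return build_context(table)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
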