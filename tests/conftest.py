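import numpy as np
import pytest

from pepscan.seqcore import AMINO_ACIDS
from pepscan.simulate import build_fixture, default_spec


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The built-in fixture touching all annotation categories."""
    out = tmp_path_factory.mktemp("default_fixture")
    return build_fixture(default_spec(seed=7), out)


def random_peptides(rng: np.random.Generator, n: int, lengths=(8, 12)) -> list[str]:
    """Random query peptides with no nesting (no peptide inside another)."""
    out: list[str] = []
    alphabet = list(AMINO_ACIDS)
    while len(out) < n:
        length = int(rng.integers(lengths[0], lengths[1] + 1))
        pep = "".join(rng.choice(alphabet, size=length))
        collapsed = pep.replace("I", "L")
        if any(collapsed in q or q in collapsed
               for q in (p.replace("I", "L") for p in out)):
            continue
        out.append(pep)
    return out
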