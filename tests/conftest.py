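import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from helpers import pdb_line

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def simple_pdb_text():
    """Three protein residues around the origin, a ligand, waters, a metal."""
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, -1.0, 0.0, 0.0, element="N"),
        pdb_line(2, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, element="C"),
        pdb_line(3, "C", "ALA", "A", 1, 1.2, 0.3, 0.0, element="C"),
        pdb_line(4, "O", "ALA", "A", 1, 1.8, 1.2, 0.4, element="O"),
        pdb_line(5, "CB", "ALA", "A", 1, 0.2, -1.4, 0.3, occ=0.6,
                 element="C", altloc="A"),
        pdb_line(6, "CB", "ALA", "A", 1, 0.3, -1.5, 0.2, occ=0.4,
                 element="C", altloc="B"),
        pdb_line(7, "SG", "CYS", "A", 2, 3.0, 3.0, 3.0, element="S"),
        pdb_line(8, "CA", "GLY", "A", 3, 30.0, 30.0, 30.0, element="C"),
        pdb_line(9, "C1", "LIG", "B", 1, 0.5, 0.5, 0.5, element="C",
                 record="HETATM"),
        pdb_line(10, "N1", "LIG", "B", 1, 1.5, 0.5, 0.5, element="N",
                 record="HETATM"),
        pdb_line(11, "O", "HOH", "B", 2, 2.0, 2.0, 2.0, element="O",
                 record="HETATM"),
        pdb_line(12, "ZN", "ZN", "B", 3, 4.0, 4.0, 4.0, element="ZN",
                 record="HETATM"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def small_trained():
    """A small surrogate trained on synthetic-oracle data, with its truth.

    Shared across tests that need a usable (not highly accurate) trained
    model: screening, checkpointing, ranking.
    """
    from surrodock import model as md
    from surrodock import synthetic as sy

    examples, truth = sy.make_dataset(300, seed=42, n_iter=200)
    config = md.ModelConfig(n_blocks=3, hidden=48, learning_rate=1e-3,
                            epochs=25, batch_size=64, seed=42)
    results = md.DockingSurrogate(examples, config).fit()
    params = sy.OracleParams.from_seed(42)
    return results, truth, params
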