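import numpy as np
import pytest

from assemblyqa.decoys import DecoyEnsembleSpec, NoiseTier, make_decoys, make_native
from assemblyqa.structures import Chain, Residue, StructureModel


def toy_model(chains: dict[str, list[tuple[int, str, dict[str, tuple]]]],
              model_id: str = "toy", target_id: str = "T") -> StructureModel:
    """Build a model from {chain_id: [(resnum, resname, {atom: xyz}), ...]}."""
    built = []
    for cid, residues in chains.items():
        built.append(Chain(cid, [
            Residue(num, name, {a: np.array(x, float) for a, x in atoms.items()})
            for num, name, atoms in residues
        ]))
    return StructureModel(model_id, target_id, built)


@pytest.fixture(scope="session")
def homo_spec():
    return DecoyEnsembleSpec(n_chains=2, chain_lengths=(24, 24), stoichiometry="homo",
                             n_decoys=10, seed=11)


@pytest.fixture(scope="session")
def hetero_spec():
    return DecoyEnsembleSpec(n_chains=2, chain_lengths=(24, 20), stoichiometry="hetero",
                             n_decoys=10, seed=12)


@pytest.fixture(scope="session")
def homo_native(homo_spec):
    return make_native(homo_spec)


@pytest.fixture(scope="session")
def hetero_native(hetero_spec):
    return make_native(hetero_spec)


@pytest.fixture(scope="session")
def homo_decoys(homo_native, homo_spec):
    return make_decoys(homo_native, homo_spec)


@pytest.fixture(scope="session")
def hetero_decoys(hetero_native, hetero_spec):
    return make_decoys(hetero_native, hetero_spec)


@pytest.fixture()
def mild_tier():
    return NoiseTier(0.3, 0.5, 0.2, 1.0)
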