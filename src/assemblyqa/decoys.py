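"""Synthetic native complexes and graded decoy populations.

Quality-assessment pipelines are exercised here on idealised toy assemblies:
each chain is a poly-alanine-geometry alpha-helix (N, CA, C, O and CB heavy
atoms built from ideal local frames; glycines carry no CB), and chains are
docked side by side on a ring so that every neighbouring chain pair forms a
genuine interface (>= 5 heavy-atom contacts at 5 A).  Decoys of graded
quality are produced by per-chain rigid-body perturbation plus i.i.d.
Gaussian coordinate noise, optionally with chain labels permuted among
sequence-identical chains to exercise the chain-mapping machinery.

The generator emulates the *population structure* of a blind-prediction
model set — a quality ladder from near-native to dissociated — not the
physics of real proteins: there is no side-chain packing, no secondary-
structure variety, and noise is isotropic.  A two-cluster "conformational
heterogeneity" preset reproduces the classic failure mode of consensus
scoring, where models of a minority conformation are scored down by a jury
dominated by the other cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Chain, Residue, StructureModel

__all__ = [
    "NoiseTier",
    "DecoyEnsembleSpec",
    "make_native",
    "make_decoys",
    "make_two_cluster_population",
    "DEFAULT_LADDER",
]

_AMINO = "ACDEFHIKLMNPQRSTVWY"  # G excluded from random draws; added explicitly

# helix geometry: 100 deg turn and 1.5 A rise per residue, 2.3 A radius
_TURN = np.deg2rad(100.0)
_RISE = 1.5
_RADIUS = 2.3
# spacing between neighbouring chain axes: close enough for a contact-rich
# interface at 5 A, far enough that nothing clashes below 2.2 A
_AXIS_SPACING = 9.5
_MIN_NATIVE_CONTACTS = 5


@dataclass(frozen=True)
class NoiseTier:
    """One rung of the decoy quality ladder."""

    sigma_cart: float      # per-atom Gaussian noise, A
    rigid_rot_deg: float   # per-chain rigid rotation magnitude, degrees
    rigid_trans: float     # per-chain rigid translation magnitude, A
    fraction: float        # share of the population drawn at this tier


# spans observed scores from 1.0 down to the dissociated regime
DEFAULT_LADDER: tuple[NoiseTier, ...] = (
    NoiseTier(0.0, 0.0, 0.0, 0.2),
    NoiseTier(0.5, 1.0, 0.25, 0.2),
    NoiseTier(1.0, 2.0, 0.5, 0.2),
    NoiseTier(2.0, 4.0, 1.0, 0.2),
    NoiseTier(4.0, 8.0, 2.0, 0.2),
)


@dataclass
class DecoyEnsembleSpec:
    """Parameters of one synthetic model population."""

    n_chains: int = 2
    chain_lengths: tuple[int, ...] = (24, 24)
    stoichiometry: str = "homo"          # "homo" | "hetero"
    n_decoys: int = 30
    noise_ladder: tuple[NoiseTier, ...] = DEFAULT_LADDER
    permute_labels: bool = False
    seed: int = 0
    target_id: str = "T0001"

    def __post_init__(self) -> None:
        if not 2 <= self.n_chains <= 4:
            raise ValueError("n_chains must be between 2 and 4")
        if len(self.chain_lengths) == 1:
            self.chain_lengths = self.chain_lengths * self.n_chains
        if len(self.chain_lengths) != self.n_chains:
            raise ValueError("chain_lengths must match n_chains")
        if any(l < 20 or l > 80 for l in self.chain_lengths):
            raise ValueError("chain lengths must be within 20..80 residues")
        if self.stoichiometry not in ("homo", "hetero"):
            raise ValueError("stoichiometry must be 'homo' or 'hetero'")
        if self.stoichiometry == "homo" and len(set(self.chain_lengths)) != 1:
            raise ValueError("homomeric chains must share one length")
        total = sum(t.fraction for t in self.noise_ladder)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("tier fractions must sum to 1")
        if any(t.sigma_cart < 0 for t in self.noise_ladder):
            raise ValueError("noise sigma must be non-negative")


# ---------------------------------------------------------------------------
# native construction

def _helix_atoms(n_res: int) -> list[dict[str, np.ndarray]]:
    """Heavy atoms of an idealised helical segment centred on the z axis."""
    t = np.arange(n_res)
    ca = np.stack([
        _RADIUS * np.cos(_TURN * t),
        _RADIUS * np.sin(_TURN * t),
        _RISE * t,
    ], axis=1)
    atoms = []
    for i in range(n_res):
        p = ca[i]
        u_next = ca[i + 1] - p if i + 1 < n_res else p - ca[i - 1]
        u_prev = ca[i - 1] - p if i > 0 else p - ca[i + 1]
        u_next = u_next / np.linalg.norm(u_next)
        u_prev = u_prev / np.linalg.norm(u_prev)
        outward = np.array([p[0], p[1], 0.0])
        outward = outward / np.linalg.norm(outward)
        n_at = p + 1.2 * u_prev
        c_at = p + 1.25 * u_next
        o_at = c_at + 1.23 * outward
        cb_at = p + 1.53 * outward
        atoms.append({"N": n_at, "CA": p, "C": c_at, "O": o_at, "CB": cb_at})
    return atoms


def _chain_offsets(n_chains: int) -> list[np.ndarray]:
    """Chain axis positions: a pair, a triangle or a square of side _AXIS_SPACING."""
    s = _AXIS_SPACING
    if n_chains == 2:
        pts = [(0, 0), (s, 0)]
    elif n_chains == 3:
        pts = [(0, 0), (s, 0), (s / 2, s * np.sqrt(3) / 2)]
    else:
        pts = [(0, 0), (s, 0), (s, s), (0, s)]
    return [np.array([x, y, 0.0]) for x, y in pts]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    letters = list(_AMINO)
    seq = [letters[int(k)] for k in rng.integers(0, len(letters), size=length)]
    # sprinkle a couple of glycines so the Calpha fallback of Cbeta-based
    # scores is exercised
    for pos in rng.choice(length, size=max(1, length // 12), replace=False):
        seq[int(pos)] = "G"
    return "".join(seq)


def make_native(spec: DecoyEnsembleSpec) -> StructureModel:
    """Deterministic idealised native complex for a population spec."""
    rng = np.random.default_rng(spec.seed)
    if spec.stoichiometry == "homo":
        seq = _random_sequence(rng, spec.chain_lengths[0])
        sequences = [seq] * spec.n_chains
    else:
        sequences = [_random_sequence(rng, l) for l in spec.chain_lengths]

    offsets = _chain_offsets(spec.n_chains)
    chains: list[Chain] = []
    from .structures import _CHAIN_LABELS, _ONE_TO_THREE

    for ci, (seq, off) in enumerate(zip(sequences, offsets)):
        atoms = _helix_atoms(len(seq))
        residues = []
        for i, (aa, res_atoms) in enumerate(zip(seq, atoms)):
            placed = {}
            for name, xyz in res_atoms.items():
                if aa == "G" and name == "CB":
                    continue
                placed[name] = xyz + off
            residues.append(Residue(number=i + 1, name=_ONE_TO_THREE[aa], atoms=placed))
        chains.append(Chain(chain_id=_CHAIN_LABELS[ci], residues=residues))

    native = StructureModel(model_id="native", target_id=spec.target_id, chains=chains)
    native.validate()

    from .metrics import compute_contact_map

    cmap = compute_contact_map(native, 5.0)
    if len(cmap) < _MIN_NATIVE_CONTACTS:
        raise ValueError(
            f"native geometry yields only {len(cmap)} inter-chain contacts; "
            f"need >= {_MIN_NATIVE_CONTACTS}"
        )
    return native


# ---------------------------------------------------------------------------
# decoy construction

def _random_rotation(rng: np.random.Generator, angle_deg: float) -> np.ndarray:
    """Rotation by exactly ``angle_deg`` about a uniformly random axis."""
    if angle_deg == 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _tier_allocation(spec: DecoyEnsembleSpec) -> list[int]:
    """Deterministic tier index per decoy honouring the ladder fractions."""
    counts = [int(np.floor(t.fraction * spec.n_decoys)) for t in spec.noise_ladder]
    i = 0
    while sum(counts) < spec.n_decoys:
        counts[i % len(counts)] += 1
        i += 1
    out = []
    for tier_idx, c in enumerate(counts):
        out.extend([tier_idx] * c)
    return out


def _perturb(native: StructureModel, tier: NoiseTier, rng: np.random.Generator,
             permute: bool, model_id: str, tier_index: int) -> StructureModel:
    chains: list[Chain] = []
    for chain in native.chains:
        all_xyz = np.array([xyz for r in chain.residues for xyz in r.atoms.values()])
        centroid = all_xyz.mean(axis=0)
        rot = _random_rotation(rng, tier.rigid_rot_deg)
        if tier.rigid_trans > 0:
            direction = rng.normal(size=3)
            trans = tier.rigid_trans * direction / np.linalg.norm(direction)
        else:
            trans = np.zeros(3)
        residues = []
        for res in chain.residues:
            atoms = {}
            for name, xyz in res.atoms.items():
                moved = rot @ (xyz - centroid) + centroid + trans
                if tier.sigma_cart > 0:
                    moved = moved + rng.normal(0.0, tier.sigma_cart, size=3)
                atoms[name] = moved
            residues.append(Residue(number=res.number, name=res.name, atoms=atoms))
        chains.append(Chain(chain_id=chain.chain_id, residues=residues))

    if permute:
        # relabel among sequence-identical chains only
        seqs = [c.sequence for c in chains]
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(seqs):
            groups.setdefault(s, []).append(i)
        labels = [c.chain_id for c in chains]
        for idxs in groups.values():
            if len(idxs) > 1:
                perm = rng.permutation(len(idxs))
                old = [labels[i] for i in idxs]
                for k, i in enumerate(idxs):
                    chains[i].chain_id = old[int(perm[k])]
        chains.sort(key=lambda c: c.chain_id)

    decoy = StructureModel(model_id=model_id, target_id=native.target_id, chains=chains)
    decoy.tier_index = tier_index  # ground-truth quality rung
    return decoy


def make_decoys(native: StructureModel, spec: DecoyEnsembleSpec) -> list[StructureModel]:
    """Graded decoy population for a native; each decoy carries its ladder
    tier index as ``model.tier_index`` ground truth."""
    rng = np.random.default_rng(spec.seed + 1)
    tiers = _tier_allocation(spec)
    decoys = []
    width = len(str(max(len(tiers), 1)))
    for k, tier_idx in enumerate(tiers):
        tier = spec.noise_ladder[tier_idx]
        permute = spec.permute_labels and spec.stoichiometry == "homo"
        decoys.append(
            _perturb(native, tier, rng, permute,
                     model_id=f"decoy_{k:0{width}d}", tier_index=tier_idx)
        )
    return decoys


# ---------------------------------------------------------------------------
# conformational heterogeneity preset

def make_two_cluster_population(spec: DecoyEnsembleSpec, n_per_cluster: int = 10,
                                sigma: float = 0.5
                                ) -> tuple[StructureModel, StructureModel, list[StructureModel]]:
    """Two distinct native-like conformations with mild-noise decoys around each.

    Conformation B differs from A by a 180-degree flip of the last chain about
    its own axis — a different interface, as with targets crystallised in
    alternative conformations.  Returns (native_a, native_b, population); the
    population interleaves the clusters and tags each model with
    ``cluster`` = "A" or "B".
    """
    native_a = make_native(spec)
    # flip the final chain about its own z axis
    chains_b = []
    for ci, chain in enumerate(native_a.chains):
        residues = []
        flip = ci == len(native_a.chains) - 1
        if flip:
            xyz_all = np.array([x for r in chain.residues for x in r.atoms.values()])
            centroid = xyz_all.mean(axis=0)
            rot = np.diag([-1.0, -1.0, 1.0])  # 180 deg about z
        for res in chain.residues:
            atoms = {}
            for name, xyz in res.atoms.items():
                atoms[name] = rot @ (xyz - centroid) + centroid if flip else xyz.copy()
            residues.append(Residue(res.number, res.name, atoms))
        chains_b.append(Chain(chain.chain_id, residues))
    native_b = StructureModel("native_b", spec.target_id, chains_b)

    tier = NoiseTier(sigma, 0.0, 0.0, 1.0)
    rng = np.random.default_rng(spec.seed + 2)
    population = []
    for k in range(n_per_cluster):
        a = _perturb(native_a, tier, rng, False, f"clusterA_{k:02d}", 0)
        a.cluster = "A"
        b = _perturb(native_b, tier, rng, False, f"clusterB_{k:02d}", 0)
        b.cluster = "B"
        population.extend([a, b])
    return native_a, native_b, population
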