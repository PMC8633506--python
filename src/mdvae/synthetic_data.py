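"""Synthetic two-metastable-state trajectories with known ground truth.

A toy "protein" hops between two reference conformations under a
symmetric two-state Markov chain; each frame is the active state centre
plus isotropic Gaussian positional noise, optionally followed by a
random rigid motion (uniform SO(3) rotation + translation in a box).
Every downstream stage — featurize, train, evaluate, sample,
timescales — can run against these trajectories with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import TrajectoryEnsemble, generic_atom_records

__all__ = [
    "ToyEnsembleConfig",
    "default_state_centers",
    "generate_two_state_trajectory",
    "generate_markov_chain",
    "random_rotation",
    "write_labels",
]

#: side of the cube (Å) from which random rigid-motion translations are drawn
TRANSLATION_BOX = 10.0


def default_state_centers(n_atoms: int = 50, separation_scale: float = 1.0):
    """Two reference conformations of a pseudo-atom chain: a straight
    chain and a bent (hairpin-like) chain, ~5 Å apart in superposition
    RMSD at the default size — far enough apart that a 2-D latent space
    must separate them.
    """
    spacing = 1.5
    t = np.arange(n_atoms, dtype=float)
    straight = np.stack([spacing * t, np.zeros(n_atoms), np.zeros(n_atoms)], axis=1)
    # bend the second half of the chain out of the x-axis; 48 deg gives
    # ~5 A superposition RMSD between the two centres at n_atoms=50
    bent = straight.copy()
    half = n_atoms // 2
    s = np.arange(n_atoms - half, dtype=float)
    theta = np.deg2rad(48.0) * separation_scale
    bent[half:, 0] = straight[half - 1, 0] + spacing * s * np.cos(theta)
    bent[half:, 1] = spacing * s * np.sin(theta)
    return straight, bent


@dataclass
class ToyEnsembleConfig:
    """Parameters of the two-state toy trajectory generator.

    noise_sigma is the per-coordinate isotropic Gaussian width (Å);
    switch_prob the per-step probability of hopping to the other state
    (symmetric two-state Markov chain started in state 0).
    """

    n_atoms: int = 50
    n_frames: int = 1000
    state_centers: tuple[np.ndarray, np.ndarray] = None  # type: ignore[assignment]
    noise_sigma: float = 0.5
    switch_prob: float = 0.05
    rigid_motion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not self.noise_sigma > 0:
            raise ValueError("noise_sigma must be > 0")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must be in [0, 1]")
        if self.state_centers is None:
            self.state_centers = default_state_centers(self.n_atoms)
        a, b = (np.asarray(c, dtype=float) for c in self.state_centers)
        if a.shape != (self.n_atoms, 3) or b.shape != (self.n_atoms, 3):
            raise ValueError(
                f"state centers must each be ({self.n_atoms}, 3) arrays"
            )
        if np.allclose(a, b):
            raise ValueError("the two state centers must be distinct")
        self.state_centers = (a, b)


def generate_markov_chain(
    n_steps: int, transition_matrix: np.ndarray, seed: int
) -> np.ndarray:
    """Realise a two-state chain of length ``n_steps`` started in state 0."""
    T = np.asarray(transition_matrix, dtype=float)
    if T.shape != (2, 2):
        raise ValueError("transition_matrix must be 2x2")
    if (T < -1e-12).any() or (T > 1 + 1e-12).any():
        raise ValueError("transition probabilities must lie in [0, 1]")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition_matrix rows must sum to 1")
    rng = np.random.default_rng(seed)
    states = np.empty(n_steps, dtype=int)
    states[0] = 0
    u = rng.random(n_steps - 1)
    for t in range(1, n_steps):
        states[t] = int(u[t - 1] < T[states[t - 1], 1])
    return states


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix drawn uniformly from SO(3) via a normalised
    quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def generate_two_state_trajectory(
    config: ToyEnsembleConfig,
) -> tuple[TrajectoryEnsemble, np.ndarray]:
    """Generate frames around the two state centres.

    Frame i is ``state_centers[s_i]`` plus N(0, noise_sigma²) per
    coordinate; with ``rigid_motion`` each frame also receives an
    independent uniform rotation and a translation uniform in a
    ±TRANSLATION_BOX/2 cube.  Returns the ensemble and the ground-truth
    state labels.  A single RNG stream seeded from ``config.seed`` drives
    everything, so output is bit-identical across runs.
    """
    rng = np.random.default_rng(config.seed)
    p = config.switch_prob
    T = np.array([[1 - p, p], [p, 1 - p]])
    # chain realised from the same stream as the noise
    states = np.empty(config.n_frames, dtype=int)
    states[0] = 0
    u = rng.random(config.n_frames - 1)
    for t in range(1, config.n_frames):
        states[t] = int(u[t - 1] < T[states[t - 1], 1])

    centers = np.stack(config.state_centers)
    coords = centers[states] + rng.normal(
        scale=config.noise_sigma, size=(config.n_frames, config.n_atoms, 3)
    )
    if config.rigid_motion:
        for i in range(config.n_frames):
            R = random_rotation(rng)
            t_vec = rng.uniform(-TRANSLATION_BOX / 2, TRANSLATION_BOX / 2, size=3)
            coords[i] = coords[i] @ R.T + t_vec
    traj = TrajectoryEnsemble(coords, generic_atom_records(config.n_atoms))
    return traj, states


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    """One integer state label per line."""
    path = Path(path)
    path.write_text("\n".join(str(int(s)) for s in labels) + "\n")
    return path
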