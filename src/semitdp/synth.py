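"""Synthetic fixtures: digit-like binary images and abstract voter tables.

The image fixture emulates a small binarized handwritten-digit task without
any external download: each class has a distinct stroke prototype (vertical
bar, ring, diagonal, angle) drawn on a square canvas, and samples are the
prototype corrupted by independent pixel flips.  Distinct stroke geometry
means partial-feature ensemble members genuinely see different evidence,
which is what makes feature selection matter.

The voter fixture builds firing-probability tables with controlled
discriminability for the logical ensemble model: on a sample of class c the
designated neuron carries ``discriminability`` probability mass and the rest
is spread uniformly, so chance-level tables (mass 1/N_C) have NCE = 0.5 and
perfect tables (mass 1) have NCE = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .logical import VoterTable

__all__ = ["DigitFixtureSpec", "VoterFixtureSpec", "make_digits", "make_voters"]


@dataclass
class DigitFixtureSpec:
    n_classes: int = 4
    samples_per_class: int = 700
    image_side: int = 28
    flip_rate: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.flip_rate < 0.5):
            raise ValueError("flip rate must lie in [0, 0.5)")
        if self.n_classes < 2 or self.n_classes > 4:
            raise ValueError("between 2 and 4 stroke prototypes are available")


@dataclass
class VoterFixtureSpec:
    n_classes: int = 4
    ensemble_size: int = 3
    samples_per_class: int = 4
    discriminability: float | list[float] = 0.7
    gating_discriminability: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        lo = 1.0 / self.n_classes
        for d in np.atleast_1d(np.asarray(self.discriminability, dtype=float)):
            if not (lo <= d <= 1.0):
                raise ValueError(f"discriminability must lie in [{lo}, 1]")
        if not (lo <= self.gating_discriminability <= 1.0):
            raise ValueError(f"gating discriminability must lie in [{lo}, 1]")


def _prototype(class_id: int, side: int) -> np.ndarray:
    """Distinct stroke glyph per class, drawn with ~3px-wide strokes."""
    img = np.zeros((side, side), dtype=np.uint8)
    m = max(side // 7, 2)  # margin
    w = max(side // 9, 2)  # stroke width
    if class_id == 0:  # vertical bar
        c = side // 2
        img[m : side - m, c - w // 2 : c - w // 2 + w] = 1
    elif class_id == 1:  # ring
        yy, xx = np.mgrid[0:side, 0:side]
        c = (side - 1) / 2.0
        r = np.hypot(yy - c, xx - c)
        r_out = side / 2.0 - m
        img[(r <= r_out) & (r >= r_out - w)] = 1
    elif class_id == 2:  # diagonal
        for d in range(-(w // 2), w - w // 2):
            idx = np.arange(m, side - m)
            jdx = np.clip(idx + d, 0, side - 1)
            img[idx, jdx] = 1
    else:  # angle (L shape)
        img[m : side - m, m : m + w] = 1
        img[side - m - w : side - m, m : side - m] = 1
    return img


def make_digits(spec: DigitFixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate (images, labels): images of shape (N, side, side) in {0,1},
    labels in [0, n_classes).  Bit-identical for the same spec."""
    rng = np.random.default_rng(spec.seed)
    protos = [_prototype(c, spec.image_side) for c in range(spec.n_classes)]
    images = []
    labels = []
    for c, proto in enumerate(protos):
        flips = rng.random((spec.samples_per_class, *proto.shape)) < spec.flip_rate
        samples = np.where(flips, 1 - proto[None], proto[None]).astype(np.uint8)
        images.append(samples)
        labels.append(np.full(spec.samples_per_class, c))
    return np.concatenate(images), np.concatenate(labels)


def _discriminable_table(
    n_classes: int,
    labels: np.ndarray,
    target_neuron_of_class: np.ndarray,
    discriminability: float,
) -> np.ndarray:
    m = labels.size
    probs = np.full((m, n_classes), (1.0 - discriminability) / (n_classes - 1))
    probs[np.arange(m), target_neuron_of_class[labels]] = discriminability
    return probs


def make_voters(spec: VoterFixtureSpec) -> tuple[list[VoterTable], VoterTable]:
    """Construct ensemble voter tables plus a gating table.

    Per sample of class c the voter's designated neuron for c receives
    ``discriminability`` mass and the remainder is uniform over the other
    neurons.  Each voter gets its own random permutation mapping classes to
    neuron indices (class identity need not match neuron index); the gating
    voter uses the identity mapping so its neuron k means class k.
    """
    rng = np.random.default_rng(spec.seed)
    n_c = spec.n_classes
    labels = np.repeat(np.arange(n_c), spec.samples_per_class)
    disc = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.discriminability, dtype=float)),
        (spec.ensemble_size,),
    ) if np.ndim(spec.discriminability) == 0 else np.asarray(spec.discriminability)
    if disc.size != spec.ensemble_size:
        raise ValueError("need one discriminability per ensemble member")
    voters = []
    for j in range(spec.ensemble_size):
        perm = rng.permutation(n_c)
        voters.append(
            VoterTable(
                _discriminable_table(n_c, labels, perm, float(disc[j])),
                labels=labels,
            )
        )
    gate = VoterTable(
        _discriminable_table(
            n_c, labels, np.arange(n_c), spec.gating_discriminability
        ),
        labels=labels,
    )
    return voters, gate


def analytic_voter_joint(table: VoterTable) -> np.ndarray:
    """Joint p(class, neuron) implied by a voter table under uniform sample
    presentation — the analytic counterpart of counting spikes."""
    if table.labels is None:
        raise ValueError("voter table must carry labels")
    n_c = table.n_neurons
    joint = np.zeros((n_c, n_c))
    for c in range(n_c):
        rows = table.probs[table.labels == c]
        joint[c] = rows.sum(axis=0)
    return joint / joint.sum()
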