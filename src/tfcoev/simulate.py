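"""Synthetic TF families with known ground truth.

The generator emits an aligned DBD family with planted structure so that
every downstream stage can be validated without external downloads:

* ``n_subclass`` subclasses of TFs, each with its own PWM template;
* subclass-determining columns (one subclass-specific residue per subclass,
  with a configurable within-subclass substitution rate);
* covarying column pairs: the second column is the image of the first under
  a fixed random bijection of the residue alphabet with probability equal to
  the coupling, and an independent uniform draw otherwise — at coupling 1
  the pair's mutual information equals the first column's entropy;
* background columns drawn i.i.d. uniform over an alphabet subset;
* per-TF PWMs sampled column-wise from Dirichlet(alpha x template + 1).

Toy protein-DNA complexes with hand-placed atoms provide exact distance
oracles for the structure stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .msa import AA_ALPHABET, AlignedFamily
from .motifs import BASES, PositionWeightMatrix, PwmSet, motif_similarity
from .structure import AA_THREE_TO_ONE, DNA_RESIDUES, StructureComplex, load_complex

AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}
MAX_TEMPLATE_SIMILARITY = 0.5  # subclass templates are separated by construction


class ConfigurationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    n_tf: int = 60
    n_col: int = 40
    n_subclass: int = 3
    tsds_columns: list[int] = field(default_factory=list)
    coevolving_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    background_alphabet_size: int = 20
    pwm_width: int = 8
    pwm_noise: float = 50.0  # Dirichlet concentration multiplier
    tsds_noise: float = 0.05  # within-subclass substitution rate at TSDS columns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subclass < 1:
            raise ConfigurationError("n_subclass must be >= 1")
        if self.n_subclass > self.n_tf:
            raise ConfigurationError("n_subclass exceeds n_tf")
        if not 1 <= self.background_alphabet_size <= 20:
            raise ConfigurationError("background_alphabet_size must be in [1, 20]")
        if self.pwm_noise <= 0:
            raise ConfigurationError("pwm_noise must be positive")
        planted: list[int] = list(self.tsds_columns)
        for i, j, rho in self.coevolving_pairs:
            if not 0.0 <= rho <= 1.0:
                raise ConfigurationError(f"coupling {rho} outside [0, 1]")
            planted.extend([i, j])
        if len(set(planted)) != len(planted):
            raise ConfigurationError("planted columns overlap")
        out_of_range = [c for c in planted if not 0 <= c < self.n_col]
        if out_of_range:
            raise ConfigurationError(f"planted columns out of range: {out_of_range}")
        if self.n_subclass > self.background_alphabet_size and self.tsds_columns:
            raise ConfigurationError(
                "need at least n_subclass distinct residues for TSDS columns"
            )


@dataclass
class SyntheticTruth:
    subclass_of: dict[str, int]
    true_tsds: set[int]
    true_pairs: set[tuple[int, int]]
    pwm_templates: dict[int, PositionWeightMatrix]
    couplings: dict[tuple[int, int], float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "subclass_of": self.subclass_of,
            "true_tsds": sorted(self.true_tsds),
            "true_pairs": [
                [i, j, self.couplings.get((i, j))] for i, j in sorted(self.true_pairs)
            ],
            "pwm_templates": {
                str(s): t.matrix.tolist() for s, t in self.pwm_templates.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def generate_family(
    config: SyntheticConfig,
) -> tuple[AlignedFamily, PwmSet, SyntheticTruth]:
    """Generate an aligned family, per-TF PWMs, and the planted truth."""
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(AA_ALPHABET[: config.background_alphabet_size]))
    n, L, S = config.n_tf, config.n_col, config.n_subclass

    subclass = np.array([t % S for t in range(n)])
    ids = [f"TF{t:04d}" for t in range(n)]

    # background: every column i.i.d. uniform over the alphabet subset
    seqs = alphabet[rng.integers(len(alphabet), size=(n, L))]

    # subclass-determining columns
    for c in config.tsds_columns:
        residues = rng.choice(alphabet, size=S, replace=False)
        seqs[:, c] = residues[subclass]
        noisy = rng.random(n) < config.tsds_noise
        seqs[noisy, c] = alphabet[rng.integers(len(alphabet), size=int(noisy.sum()))]

    # covarying pairs: fixed random bijection per pair, applied w.p. coupling
    couplings: dict[tuple[int, int], float] = {}
    for i, j, rho in config.coevolving_pairs:
        bijection = dict(zip(alphabet, rng.permutation(alphabet)))
        follow = rng.random(n) < rho
        seqs[:, j] = np.where(
            follow,
            np.array([bijection[a] for a in seqs[:, i]]),
            alphabet[rng.integers(len(alphabet), size=n)],
        )
        couplings[(min(i, j), max(i, j))] = rho

    msa = AlignedFamily(ids, seqs, seed_id=ids[0])

    # subclass PWM templates: rejection-sampled to be mutually separated
    # under the same offset/orientation-searched similarity used downstream
    # (chance sharing of a short submotif would otherwise blur subclasses)
    templates: dict[int, PositionWeightMatrix] = {}
    for s in range(S):
        for _ in range(200):
            mat = np.full((4, config.pwm_width), 0.05)
            dominant = rng.integers(4, size=config.pwm_width)
            mat[dominant, np.arange(config.pwm_width)] = 0.85
            candidate = PositionWeightMatrix(f"template{s}", mat)
            if all(
                motif_similarity(candidate, t) <= MAX_TEMPLATE_SIMILARITY
                for t in templates.values()
            ):
                break
        else:
            raise ConfigurationError(
                f"could not draw {S} mutually separated PWM templates "
                f"of width {config.pwm_width}"
            )
        templates[s] = candidate
    pwms: PwmSet = []
    for t, tf in enumerate(ids):
        template = templates[subclass[t]].matrix
        cols = np.column_stack(
            [
                rng.dirichlet(config.pwm_noise * template[:, w] + 1.0)
                for w in range(config.pwm_width)
            ]
        )
        pwms.append(PositionWeightMatrix(tf, cols))

    truth = SyntheticTruth(
        subclass_of={tf: int(s) for tf, s in zip(ids, subclass)},
        true_tsds=set(config.tsds_columns),
        true_pairs=set(couplings),
        pwm_templates=templates,
        couplings=couplings,
    )
    return msa, pwms, truth


# ---------------------------------------------------------------------------
# Toy protein-DNA complexes
# ---------------------------------------------------------------------------

@dataclass
class PlacedResidue:
    """One residue (or nucleotide) with explicitly placed atoms."""

    chain: str
    number: int
    name: str  # three-letter amino acid or DA/DC/DG/DT/DU
    atoms: list[tuple[str, float, float, float]]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ConfigurationError(f"{self.name} {self.number}: no atoms")
        names = [a[0] for a in self.atoms]
        if len(set(names)) != len(names):
            # duplicate names inside one residue collapse on PDB re-parsing
            raise ConfigurationError(
                f"{self.name} {self.number}: duplicate atom names {names}"
            )
        known = set(AA_THREE_TO_ONE) | DNA_RESIDUES
        if self.name not in known:
            raise ConfigurationError(f"unknown residue name {self.name!r}")


def toy_complex_pdb(spec: list[PlacedResidue], resolution: float = 2.0) -> str:
    """Render placed residues as PDB-format text (with a resolution record)."""
    if not any(r.name in DNA_RESIDUES for r in spec):
        raise ConfigurationError("complex must contain a DNA chain")
    if not any(r.name in AA_THREE_TO_ONE for r in spec):
        raise ConfigurationError("complex must contain a protein chain")
    lines = [
        "HEADER    SYNTHETIC TOY COMPLEX                   01-JAN-00   XXXX",
        f"REMARK   2 RESOLUTION. {resolution:7.2f} ANGSTROMS.",
    ]
    serial = 1
    for res in spec:
        for name, x, y, z in res.atoms:
            element = name.strip()[0]
            lines.append(
                f"ATOM  {serial:>5d}  {name:<3s}{res.name:>4s} {res.chain:1s}"
                f"{res.number:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_toy_complex(
    spec: list[PlacedResidue],
    resolution: float = 2.0,
    path=None,
    structure_id: str = "toy",
) -> StructureComplex:
    """Write (optionally) and re-parse a toy complex through the PDB format."""
    text = toy_complex_pdb(spec, resolution)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
        return load_complex(path, structure_id=structure_id)
    import io as _io

    return load_complex(_io.StringIO(text), structure_id=structure_id)
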