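"""Synthetic cohorts with planted, signed transcription-factor regulons.

The generator emulates the statistical structure of the study design this
package targets: one large reference cohort used for network inference, and
small independent case-control cohorts in which the activity of a single
transcription factor (TF) is shifted between classes.

Generative model
----------------
Each TF ``t`` has a latent activity ``a_t(s) ~ Normal(0, 1)`` per sample
``s``.  Observed expression (log2 scale, centred at zero, as in log-ratio
microarray data):

* TF expression:      ``x_t = a_t + Normal(0, noise_sd)``
* target expression:  ``x_g = sum over parents (mode * weight * a_t) + Normal(0, noise_sd)``
* decoy expression:   ``x_d = Normal(0, 1)`` (independent of everything)

``mode`` is +1 for activated targets and -1 for repressed targets; the sign
of the population TF-target Pearson correlation equals ``mode``.  Under a
perturbation, case samples draw the perturbed TF's activity from
``Normal(+shift, 1)`` (induced) or ``Normal(-shift, 1)`` (repressed), so a
repressed regulon shows its positive targets down- and its negative targets
up-regulated in cases.

Optionally a TF's latent activity can be coupled to another TF's activity
(``a_b = rho * a_a + sqrt(1 - rho^2) * z``).  This creates TF-TF-target
chains whose indirect edge the data-processing-inequality filter should
remove, and is used to exercise that filter; it is off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .exceptions import InvalidInputError, InvalidParameterError
from .expression import CASE, CONTROL, ExpressionMatrix
from .regulons import Regulon

INDUCED = "induced"
REPRESSED = "repressed"


@dataclass(frozen=True)
class TargetAssignment:
    """One TF->target regulatory edge of the ground truth."""

    target: str
    mode: int  # +1 activated, -1 repressed
    weight: float  # effect size on the latent-activity scale, >= 0

    def __post_init__(self) -> None:
        if self.mode not in (-1, 1):
            raise InvalidParameterError("mode must be +1 or -1")
        if self.weight < 0:
            raise InvalidParameterError("effect weight must be >= 0")


@dataclass
class TruthNetwork:
    """Ground-truth regulatory structure used to generate cohorts.

    ``tf_ids``, regulated target ids and ``decoy_ids`` are disjoint roles;
    a target may be regulated by more than one TF.
    """

    tf_ids: list[str]
    targets: dict[str, list[TargetAssignment]]
    decoy_ids: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tf_set = set(self.tf_ids)
        tgt_set = {a.target for lst in self.targets.values() for a in lst}
        decoy_set = set(self.decoy_ids)
        if tf_set & tgt_set or tf_set & decoy_set or tgt_set & decoy_set:
            raise InvalidInputError("tf, target and decoy roles must be disjoint")
        if set(self.targets) - tf_set:
            raise InvalidInputError("targets assigned to unknown TF")

    @property
    def target_ids(self) -> list[str]:
        """Distinct regulated target ids, in first-appearance order."""
        seen: dict[str, None] = {}
        for tf in self.tf_ids:
            for a in self.targets.get(tf, []):
                seen.setdefault(a.target, None)
        return list(seen)

    @property
    def gene_ids(self) -> list[str]:
        return [*self.tf_ids, *self.target_ids, *self.decoy_ids]

    def parents_of(self, target: str) -> list[tuple[str, TargetAssignment]]:
        out = []
        for tf in self.tf_ids:
            for a in self.targets.get(tf, []):
                if a.target == target:
                    out.append((tf, a))
        return out

    def true_edges(self) -> set[tuple[str, str]]:
        """All planted (tf, target) pairs."""
        return {
            (tf, a.target) for tf in self.tf_ids for a in self.targets.get(tf, [])
        }

    # -- I/O -------------------------------------------------------------
    def write_tsv(self, path: str | Path, params_path: str | Path | None = None) -> None:
        rows = [
            (tf, a.target, a.mode, a.weight)
            for tf in self.tf_ids
            for a in self.targets.get(tf, [])
        ]
        df = pd.DataFrame(rows, columns=["tf", "target", "mode", "weight"])
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        if params_path is not None:
            sidecar = {
                "params": self.params,
                "tf_ids": self.tf_ids,
                "decoy_ids": self.decoy_ids,
            }
            Path(params_path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


@dataclass(frozen=True)
class PerturbationSpec:
    """A class-dependent shift of one TF's latent activity.

    ``activity_shift`` is the difference between case and control latent
    activity means, in latent SD units (a standardized effect size).
    """

    perturbed_tf: str
    direction: str  # "induced" or "repressed"
    activity_shift: float

    def __post_init__(self) -> None:
        if self.direction not in (INDUCED, REPRESSED):
            raise InvalidParameterError("direction must be 'induced' or 'repressed'")
        if self.activity_shift < 0:
            raise InvalidParameterError("activity_shift must be >= 0")


def make_truth_network(
    n_tf: int,
    targets_per_tf: int,
    frac_negative: float = 0.0,
    n_decoys: int = 0,
    shared_target_rate: float = 0.0,
    effect_weight: float = 1.0,
    seed: int = 0,
) -> TruthNetwork:
    """Build a ground-truth network with planted signed regulons.

    Each TF receives ``targets_per_tf`` private targets; a
    ``shared_target_rate`` fraction of all targets is additionally assigned
    to a second, different TF (creating triplets the DPI filter can act on).
    ``frac_negative`` of each TF's private targets get mode -1 (rounded to
    the nearest count); shared assignments draw their mode independently
    with probability ``frac_negative``.
    """
    if n_tf < 1 or targets_per_tf < 2:
        raise InvalidParameterError("n_tf >= 1 and targets_per_tf >= 2 required")
    if n_decoys < 0:
        raise InvalidParameterError("n_decoys must be >= 0")
    if not (0.0 <= frac_negative <= 1.0):
        raise InvalidParameterError("frac_negative must lie in [0, 1]")
    if not (0.0 <= shared_target_rate <= 1.0):
        raise InvalidParameterError("shared_target_rate must lie in [0, 1]")
    n_total = n_tf * targets_per_tf
    n_shared = int(round(shared_target_rate * n_total))
    if n_shared > 0 and n_tf < 2:
        raise InvalidParameterError("shared targets require at least 2 TFs")

    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i:03d}" for i in range(n_tf)]
    target_ids = [f"G{i:05d}" for i in range(n_total)]
    decoy_ids = [f"D{i:05d}" for i in range(n_decoys)]

    targets: dict[str, list[TargetAssignment]] = {tf: [] for tf in tf_ids}
    owner: dict[str, str] = {}
    n_neg = int(round(frac_negative * targets_per_tf))
    for i, tf in enumerate(tf_ids):
        block = target_ids[i * targets_per_tf : (i + 1) * targets_per_tf]
        neg_pos = set(rng.choice(targets_per_tf, size=n_neg, replace=False).tolist())
        for j, g in enumerate(block):
            mode = -1 if j in neg_pos else 1
            targets[tf].append(TargetAssignment(g, mode, effect_weight))
            owner[g] = tf

    if n_shared > 0:
        shared = rng.choice(n_total, size=n_shared, replace=False)
        for idx in sorted(shared.tolist()):
            g = target_ids[idx]
            others = [t for t in tf_ids if t != owner[g]]
            second = others[int(rng.integers(len(others)))]
            mode = -1 if rng.random() < frac_negative else 1
            targets[second].append(TargetAssignment(g, mode, effect_weight))

    params = {
        "n_tf": n_tf,
        "targets_per_tf": targets_per_tf,
        "frac_negative": frac_negative,
        "n_decoys": n_decoys,
        "shared_target_rate": shared_target_rate,
        "effect_weight": effect_weight,
        "seed": int(seed),
    }
    return TruthNetwork(tf_ids, targets, decoy_ids, params)


def simulate_cohort(
    truth: TruthNetwork,
    n_samples: int,
    noise_sd: float,
    perturbation: PerturbationSpec | None = None,
    n_case: int | None = None,
    seed: int = 0,
    tf_coupling: Mapping[str, tuple[str, float]] | None = None,
    sample_prefix: str = "S",
) -> ExpressionMatrix:
    """Draw one cohort from the latent-activity linear-Gaussian model.

    With a ``perturbation``, the first ``n_case`` samples are cases and get
    ``case``/``control`` labels.  ``tf_coupling`` maps a TF to
    ``(other_tf, rho)`` and replaces its latent activity by a correlated
    draw (see module docstring); coupled TFs must reference uncoupled ones.

    Deterministic for a fixed seed: regenerating with the same arguments
    reproduces the matrix exactly.
    """
    if n_samples < 2:
        raise InvalidParameterError("n_samples must be >= 2")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if perturbation is not None:
        if n_case is None:
            raise InvalidParameterError("n_case required with a perturbation")
        if n_case >= n_samples:
            raise InvalidParameterError("n_case must be < n_samples")
        if n_case < 2 or n_samples - n_case < 2:
            raise InvalidParameterError("each class needs >= 2 samples")
        if perturbation.perturbed_tf not in truth.tf_ids:
            raise InvalidParameterError(
                f"perturbed TF {perturbation.perturbed_tf!r} not in truth network"
            )
    coupling = dict(tf_coupling or {})
    for tf, (src, rho) in coupling.items():
        if tf not in truth.tf_ids or src not in truth.tf_ids or tf == src:
            raise InvalidParameterError("invalid TF coupling specification")
        if src in coupling:
            raise InvalidParameterError("coupling source must itself be uncoupled")
        if not (-1.0 <= rho <= 1.0):
            raise InvalidParameterError("coupling rho must lie in [-1, 1]")

    rng = np.random.default_rng(seed)
    n_tf = len(truth.tf_ids)
    tf_index = {tf: i for i, tf in enumerate(truth.tf_ids)}

    # Latent activities: base draws first so the stream layout is stable.
    base = rng.standard_normal((n_tf, n_samples))
    activity = base.copy()
    for tf, (src, rho) in sorted(coupling.items()):
        i, j = tf_index[tf], tf_index[src]
        activity[i] = rho * activity[j] + np.sqrt(1.0 - rho * rho) * base[i]
    if perturbation is not None and perturbation.activity_shift > 0:
        shift = perturbation.activity_shift
        if perturbation.direction == REPRESSED:
            shift = -shift
        activity[tf_index[perturbation.perturbed_tf], :n_case] += shift

    tf_expr = activity + noise_sd * rng.standard_normal((n_tf, n_samples))

    target_ids = truth.target_ids
    tgt_pos = {g: k for k, g in enumerate(target_ids)}
    tgt_signal = np.zeros((len(target_ids), n_samples))
    for tf in truth.tf_ids:
        for a in truth.targets.get(tf, []):
            tgt_signal[tgt_pos[a.target]] += a.mode * a.weight * activity[tf_index[tf]]
    tgt_expr = tgt_signal + noise_sd * rng.standard_normal((len(target_ids), n_samples))

    decoy_expr = rng.standard_normal((len(truth.decoy_ids), n_samples))

    values = np.vstack([tf_expr, tgt_expr, decoy_expr]) if truth.decoy_ids else np.vstack(
        [tf_expr, tgt_expr]
    )
    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    df = pd.DataFrame(values, index=truth.gene_ids, columns=sample_ids)

    labels = None
    if perturbation is not None:
        labels = pd.Series(
            [CASE] * n_case + [CONTROL] * (n_samples - n_case),
            index=sample_ids,
            name="class",
        )
    return ExpressionMatrix(df, labels)


def regulons_from_truth(truth: TruthNetwork) -> list[Regulon]:
    """Turn the planted truth table into :class:`Regulon` objects.

    The stored correlation is the planted mode (+/-1), which is the
    population sign of the TF-target Pearson correlation under the model.
    """
    out = []
    for tf in truth.tf_ids:
        tgts = {a.target: (a.mode, float(a.mode)) for a in truth.targets.get(tf, [])}
        if tgts:
            out.append(Regulon(tf=tf, targets=tgts))
    return out


def read_truth(path: str | Path, params_path: str | Path | None = None) -> TruthNetwork:
    """Read a truth table written by :meth:`TruthNetwork.write_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    params: dict = {}
    tf_ids = sorted(df["tf"].unique().tolist())
    decoy_ids: list[str] = []
    if params_path is not None:
        sidecar = json.loads(Path(params_path).read_text())
        params = sidecar.get("params", {})
        tf_ids = sidecar.get("tf_ids", tf_ids)
        decoy_ids = sidecar.get("decoy_ids", [])
    targets: dict[str, list[TargetAssignment]] = {tf: [] for tf in tf_ids}
    for row in df.itertuples(index=False):
        targets.setdefault(row.tf, []).append(
            TargetAssignment(row.target, int(row.mode), float(row.weight))
        )
    return TruthNetwork(tf_ids, targets, decoy_ids, params)
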