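"""Individualized differential structural covariance networks (IDSCN).

A structural covariance network (SCN) is the region x region matrix of
inter-subject Pearson correlations of a morphometric measure (here, cortical
thickness).  The network-template perturbation approach quantifies how a
single subject deviates from a reference population:

1. the *reference* SCN ``r_n`` is computed from the n control subjects;
2. the *perturbed* SCN ``r_{n+1}`` is recomputed after adding subject k
   to the controls;
3. the differential network is ``ΔSCN = r_{n+1} - r_n``;
4. each edge is weighted as

       Z = ΔSCN / [ (1 - r_n**2) / (n - 1) ]

   i.e. the raw correlation change rescaled by an edge-specific factor that
   shrinks with the reference correlation magnitude and grows with the
   reference sample size.  This exact form is adopted for parity with the
   published method; it is not a conventional standard-error normalization.

Z matrices are defined off-diagonal only; edges whose reference correlation
is exactly +/-1 have a vanishing denominator and are masked explicitly.

For subjects outside the reference group ("add-in" mode) the full control
set is the reference.  For reference subjects themselves the only
self-consistent construction is leave-one-out: subject k's reference is the
other n-1 controls, perturbed by re-adding k.  (Adding a control to a
reference that already contains them makes ΔSCN identically zero.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import CorticalThicknessTable

__all__ = [
    "CovarianceNetwork",
    "IDSCNMatrix",
    "IDSCNStack",
    "pearson_network",
    "reference_scn",
    "perturbed_scn",
    "idscn_z",
    "build_idscn_cohort",
]


@dataclass
class CovarianceNetwork:
    """Symmetric Pearson correlation matrix with its contributing subjects."""

    r: np.ndarray
    n_subjects: int
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        R = self.r.shape[0]
        if self.r.shape != (R, R):
            raise ValueError("correlation matrix must be square")
        if self.n_subjects < 3:
            raise ValueError("a covariance network needs at least 3 subjects")


@dataclass
class IDSCNMatrix:
    """Per-subject differential network: ``delta`` = ΔSCN and its Z weights.

    ``masked`` flags off-diagonal edges where |r_n| = 1, for which Z is
    undefined; ``z`` holds NaN there and on the diagonal.
    """

    subject_id: str
    delta: np.ndarray
    z: np.ndarray
    reference_n: int
    masked: np.ndarray


@dataclass
class IDSCNStack:
    """IDSCN z matrices for a set of subjects (shape: subjects x R x R)."""

    subject_ids: list[str]
    group: np.ndarray
    z: np.ndarray
    delta: np.ndarray
    reference_n: np.ndarray  # per-subject reference size (differs in LOO mode)
    masked: np.ndarray  # (R, R) union of masked edges across subjects

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def _thickness(data: CorticalThicknessTable | np.ndarray) -> np.ndarray:
    if isinstance(data, CorticalThicknessTable):
        return data.thickness
    return np.asarray(data, dtype=float)


def _subject_ids(data: CorticalThicknessTable | np.ndarray) -> list[str]:
    if isinstance(data, CorticalThicknessTable):
        return list(data.subject_ids)
    return [f"s{i}" for i in range(len(np.atleast_2d(data)))]


def pearson_network(X: np.ndarray, region_names: list[str] | None = None) -> np.ndarray:
    """Region x region Pearson correlation of a subjects x regions matrix.

    Two-pass (mean-centred) computation; a zero-variance region raises with
    the offending region named rather than propagating NaN.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D subjects x regions matrix with >= 3 subjects")
    Xc = X - X.mean(axis=0)
    ss = np.einsum("ij,ij->j", Xc, Xc)
    zero = np.flatnonzero(ss == 0)
    if zero.size:
        name = region_names[zero[0]] if region_names else f"column {zero[0]}"
        raise ValueError(f"region {name} is constant across subjects; correlation undefined")
    norm = np.sqrt(ss)
    r = (Xc.T @ Xc) / np.outer(norm, norm)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def reference_scn(controls: CorticalThicknessTable | np.ndarray) -> CovarianceNetwork:
    """Reference SCN ``r_n`` from the control subjects."""
    X = _thickness(controls)
    names = controls.atlas.columns if isinstance(controls, CorticalThicknessTable) else None
    r = pearson_network(X, names)
    return CovarianceNetwork(r=r, n_subjects=X.shape[0], subject_ids=_subject_ids(controls))


def perturbed_scn(
    controls: CorticalThicknessTable | np.ndarray,
    subject: np.ndarray,
    subject_id: str = "added",
    allow_member: bool = False,
) -> CovarianceNetwork:
    """Perturbed SCN ``r_{n+1}``: the reference recomputed with one subject added.

    Computed from scratch on the stacked n+1 x R matrix, so it agrees with an
    independent Pearson recomputation to machine precision by construction.
    """
    X = _thickness(controls)
    subject = np.asarray(subject, dtype=float).ravel()
    if subject.shape[0] != X.shape[1]:
        raise ValueError(
            f"subject has {subject.shape[0]} regions but controls have {X.shape[1]}"
        )
    ids = _subject_ids(controls)
    if not allow_member and subject_id in ids:
        raise ValueError(
            f"subject {subject_id!r} is already in the reference group "
            "(use leave-one-out mode for reference subjects)"
        )
    names = controls.atlas.columns if isinstance(controls, CorticalThicknessTable) else None
    stacked = np.vstack([X, subject[None, :]])
    r = pearson_network(stacked, names)
    return CovarianceNetwork(r=r, n_subjects=X.shape[0] + 1, subject_ids=ids + [subject_id])


def idscn_z(
    reference: CovarianceNetwork,
    perturbed: CovarianceNetwork,
    subject_id: str = "added",
) -> IDSCNMatrix:
    """Edge weights Z = ΔSCN / [(1 - r_n**2)/(n - 1)] for one subject."""
    rn = reference.r
    if perturbed.r.shape != rn.shape:
        raise ValueError("reference and perturbed networks have different dimensions")
    n = reference.n_subjects
    if n < 3:
        raise ValueError("reference group must have at least 3 subjects")
    delta = perturbed.r - rn
    denom = (1.0 - rn**2) / (n - 1)
    masked = (denom == 0.0)
    np.fill_diagonal(masked, False)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, delta / np.where(denom > 0, denom, 1.0), np.nan)
    np.fill_diagonal(z, np.nan)
    z[masked] = np.nan
    return IDSCNMatrix(subject_id=subject_id, delta=delta, z=z, reference_n=n, masked=masked)


def _idscn_for_subject(
    controls_X: np.ndarray,
    control_ids: list[str],
    subject: np.ndarray,
    subject_id: str,
    names: list[str] | None,
) -> IDSCNMatrix:
    ref = CovarianceNetwork(
        r=pearson_network(controls_X, names),
        n_subjects=controls_X.shape[0],
        subject_ids=control_ids,
    )
    pert = CovarianceNetwork(
        r=pearson_network(np.vstack([controls_X, subject[None, :]]), names),
        n_subjects=controls_X.shape[0] + 1,
        subject_ids=control_ids + [subject_id],
    )
    return idscn_z(ref, pert, subject_id)


def build_idscn_cohort(
    controls: CorticalThicknessTable,
    subjects: CorticalThicknessTable,
    mode: str = "add_in",
) -> IDSCNStack:
    """IDSCN z matrices for every subject in ``subjects``.

    ``add_in``
        each subject perturbs the full control reference (subjects must be
        disjoint from the controls);
    ``leave_one_out``
        for control subjects themselves: subject k's reference is the other
        n-1 controls, perturbed by re-adding k (``subjects`` must be a subset
        of ``controls``).
    """
    if mode not in ("add_in", "leave_one_out"):
        raise ValueError(f"unknown mode {mode!r}")
    names = controls.atlas.columns
    ctrl_ids = list(controls.subject_ids)
    overlap = set(ctrl_ids) & set(subjects.subject_ids)
    if mode == "add_in" and overlap:
        raise ValueError(f"subjects overlap the control reference in add_in mode: {sorted(overlap)}")
    if mode == "leave_one_out":
        missing = set(subjects.subject_ids) - set(ctrl_ids)
        if missing:
            raise ValueError(f"leave_one_out subjects not in the control group: {sorted(missing)}")

    mats: list[IDSCNMatrix] = []
    for i, sid in enumerate(subjects.subject_ids):
        x = subjects.thickness[i]
        if mode == "add_in":
            mats.append(_idscn_for_subject(controls.thickness, ctrl_ids, x, sid, names))
        else:
            k = ctrl_ids.index(sid)
            keep = np.arange(controls.n_subjects) != k
            mats.append(
                _idscn_for_subject(
                    controls.thickness[keep],
                    [c for c in ctrl_ids if c != sid],
                    x,
                    sid,
                    names,
                )
            )
    return IDSCNStack(
        subject_ids=list(subjects.subject_ids),
        group=np.asarray(subjects.group, dtype=object),
        z=np.stack([m.z for m in mats]),
        delta=np.stack([m.delta for m in mats]),
        reference_n=np.array([m.reference_n for m in mats]),
        masked=np.logical_or.reduce([m.masked for m in mats]),
    )


def cohort_z_by_group(table: CorticalThicknessTable, control_group: str, edge_index):
    """Per-group subject x edge IDSCN z arrays for a full three-group table.

    Non-control subjects perturb the full control reference (add-in);
    controls get leave-one-out networks.
    """
    controls = table.by_group(control_group)
    others = table.subset(table.group != control_group)
    stack_o = build_idscn_cohort(controls, others, mode="add_in")
    stack_c = build_idscn_cohort(controls, controls, mode="leave_one_out")
    out: dict[str, np.ndarray] = {}
    for g in table.group_labels():
        src = stack_c if g == control_group else stack_o
        out[g] = edge_index.extract(src.z)[src.group == g]
    return out
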