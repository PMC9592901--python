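"""Trainable prediction heads over the shell descriptors.

Five heads cover the per-molecule parameter set:

==============  ==========================  ==========================
head            model                       output
==============  ==========================  ==========================
charges         random forest (800 trees,   partial charge per atom (e)
                max depth 100)
atomtype        feed-forward classifier     GAFF-style type code
phase           feed-forward classifier     torsion phase gamma {0, 180} deg
periodicity     feed-forward classifier     torsion periodicity n
force constants random forests              K_b (kcal/mol/A^2),
                                            K_theta (kcal/mol/rad^2)
==============  ==========================  ==========================

The classifiers are two-hidden-layer (256, 128) ReLU networks trained with
the adaptive-moment optimizer at learning rate 0.001 and log-loss;
regressors score by mean squared error.  All training is molecule-level
80/20 split (stratifying by molecule, not by row, so no molecule leaks
between train and validation) with 5-fold grouped cross-validation on the
training portion, and is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import (accuracy_score, mean_squared_error,
                             precision_recall_fscore_support, r2_score)
from sklearn.model_selection import GroupKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .descriptors import (DEFAULT_MANIFEST, DescriptorManifest,
                          TrainingDataset, featurize_angle, featurize_atom,
                          featurize_bond, featurize_molecule,
                          featurize_torsion, canonical_torsion)
from .molgraph import InternalCoordinates, Molecule, internal_coordinates

RF_N_TREES = 800
RF_MAX_DEPTH = 100
NN_HIDDEN = (256, 128)
NN_LEARNING_RATE = 0.001
HOLDOUT_FRACTION = 0.2
CV_FOLDS = 5


@dataclass
class TrainingReport:
    """Cross-validation and held-out metrics for one trained head."""

    head: str
    fold_mse: list[float] = field(default_factory=list)
    fold_accuracy: list[float] = field(default_factory=list)
    holdout: dict = field(default_factory=dict)
    per_class: dict = field(default_factory=dict)
    seed: int = 0
    n_train: int = 0
    n_holdout: int = 0


def _split_by_molecule(dataset: TrainingDataset, seed: int,
                       holdout_fraction: float = HOLDOUT_FRACTION):
    """Molecule-stratified 80/20 row split (no molecule in both halves)."""
    names = np.array(dataset.molecule_names())
    unique = sorted(set(names))
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(unique))
    n_hold = max(1, int(round(holdout_fraction * len(unique))))
    hold_set = set(perm[:n_hold])
    mask_hold = np.array([n in hold_set for n in names])
    return ~mask_hold, mask_hold


# --------------------------------------------------------------------------
# Charge head
# --------------------------------------------------------------------------

@dataclass
class ChargeModel:
    regressor: RandomForestRegressor
    manifest: DescriptorManifest = DEFAULT_MANIFEST
    seed: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.regressor.predict(X)


def train_charge_model(dataset: TrainingDataset, seed: int,
                       cv_folds: int = CV_FOLDS
                       ) -> tuple[ChargeModel, TrainingReport]:
    """Fit the random-forest charge head with grouped CV and holdout scoring."""
    if dataset.n_rows < max(cv_folds, 2):
        raise ValueError("dataset too small")
    train_mask, hold_mask = _split_by_molecule(dataset, seed)
    Xtr, ytr = dataset.X[train_mask], dataset.y[train_mask].astype(float)
    Xho, yho = dataset.X[hold_mask], dataset.y[hold_mask].astype(float)
    groups = np.array(dataset.molecule_names())[train_mask]

    report = TrainingReport(head="charges", seed=seed,
                            n_train=len(ytr), n_holdout=len(yho))
    n_groups = len(set(groups))
    if cv_folds and n_groups >= cv_folds:
        gkf = GroupKFold(n_splits=cv_folds)
        for tr, va in gkf.split(Xtr, ytr, groups):
            rf = RandomForestRegressor(n_estimators=RF_N_TREES,
                                       max_depth=RF_MAX_DEPTH,
                                       random_state=seed, n_jobs=1)
            rf.fit(Xtr[tr], ytr[tr])
            report.fold_mse.append(
                float(mean_squared_error(ytr[va], rf.predict(Xtr[va]))))

    final = RandomForestRegressor(n_estimators=RF_N_TREES,
                                  max_depth=RF_MAX_DEPTH,
                                  random_state=seed, n_jobs=1)
    final.fit(Xtr, ytr)
    pred = final.predict(Xho)
    report.holdout = {"mse": float(mean_squared_error(yho, pred)),
                      "r2": float(r2_score(yho, pred))}
    return ChargeModel(regressor=final, seed=seed), report


def predict_charges(model: ChargeModel, mol: Molecule) -> np.ndarray:
    """Raw (pre-normalization) per-atom charges in e."""
    return model.predict(featurize_molecule(mol, model.manifest))


# --------------------------------------------------------------------------
# Classifier heads
# --------------------------------------------------------------------------

_HEADS = ("atomtype", "phase", "periodicity")


@dataclass
class ClassifierModel:
    pipeline: Pipeline
    head: str
    classes: tuple
    manifest: DescriptorManifest = DEFAULT_MANIFEST
    seed: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(X)


def _make_classifier(seed: int) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("nn", MLPClassifier(hidden_layer_sizes=NN_HIDDEN,
                             activation="relu", solver="adam",
                             learning_rate_init=NN_LEARNING_RATE,
                             max_iter=400, random_state=seed)),
    ])


def train_classifier(head: str, dataset: TrainingDataset, seed: int,
                     cv_folds: int = CV_FOLDS
                     ) -> tuple[ClassifierModel, TrainingReport]:
    """Fit a feed-forward classification head (atomtype/phase/periodicity)."""
    if head not in _HEADS:
        raise ValueError(f"unknown head: {head}")
    labels = np.asarray(dataset.y)
    if len(set(labels.tolist())) < 2:
        raise ValueError("degenerate labels")
    train_mask, hold_mask = _split_by_molecule(dataset, seed)
    Xtr, ytr = dataset.X[train_mask], labels[train_mask]
    Xho, yho = dataset.X[hold_mask], labels[hold_mask]
    groups = np.array(dataset.molecule_names())[train_mask]

    report = TrainingReport(head=head, seed=seed,
                            n_train=len(ytr), n_holdout=len(yho))
    n_groups = len(set(groups))
    if cv_folds and n_groups >= cv_folds:
        gkf = GroupKFold(n_splits=cv_folds)
        for tr, va in gkf.split(Xtr, ytr, groups):
            if len(set(ytr[tr].tolist())) < 2:
                continue
            clf = _make_classifier(seed)
            clf.fit(Xtr[tr], ytr[tr])
            report.fold_accuracy.append(
                float(accuracy_score(ytr[va], clf.predict(Xtr[va]))))

    final = _make_classifier(seed)
    final.fit(Xtr, ytr)
    pred = final.predict(Xho)
    report.holdout = {"accuracy": float(accuracy_score(yho, pred))}
    classes = final.named_steps["nn"].classes_
    prec, rec, f1, support = precision_recall_fscore_support(
        yho, pred, labels=classes, zero_division=0)
    report.per_class = {
        str(c): {"precision": float(p), "recall": float(r),
                 "f1": float(f), "support": int(s)}
        for c, p, r, f, s in zip(classes, prec, rec, f1, support)}
    return (ClassifierModel(pipeline=final, head=head,
                            classes=tuple(classes.tolist()), seed=seed),
            report)


def predict_atom_types(model: ClassifierModel, mol: Molecule) -> list[str]:
    return [str(c) for c in model.predict(featurize_molecule(mol, model.manifest))]


def predict_torsion_params(phase_model: ClassifierModel,
                           periodicity_model: ClassifierModel,
                           mol: Molecule
                           ) -> dict[tuple[int, int, int, int],
                                     tuple[float, int]]:
    """One (gamma, n) pair per proper torsion, keyed by canonical quadruple."""
    ic = internal_coordinates(mol)
    if not ic.torsions:
        return {}
    quads = [canonical_torsion(t[:4]) for t in ic.torsions]
    X = np.vstack([featurize_torsion(mol, q, phase_model.manifest).values
                   for q in quads])
    gammas = phase_model.predict(X)
    ns = periodicity_model.predict(X)
    return {q: (float(g), int(n)) for q, g, n in zip(quads, gammas, ns)}


# --------------------------------------------------------------------------
# Force-constant head
# --------------------------------------------------------------------------

@dataclass
class ForceConstantModel:
    bond_regressor: RandomForestRegressor
    angle_regressor: RandomForestRegressor
    manifest: DescriptorManifest = DEFAULT_MANIFEST
    seed: int = 0


def train_force_constants(bond_ds: TrainingDataset, angle_ds: TrainingDataset,
                          seed: int, n_trees: int = 200
                          ) -> tuple[ForceConstantModel, TrainingReport]:
    """Fit the bond/angle force-constant regressors (holdout MSE reported)."""
    report = TrainingReport(head="force_constants", seed=seed)
    models = {}
    for name, ds in (("bond", bond_ds), ("angle", angle_ds)):
        if ds.n_rows < 2:
            raise ValueError("dataset too small")
        tr_mask, ho_mask = _split_by_molecule(ds, seed)
        rf = RandomForestRegressor(n_estimators=n_trees,
                                   max_depth=RF_MAX_DEPTH,
                                   random_state=seed, n_jobs=1)
        rf.fit(ds.X[tr_mask], ds.y[tr_mask].astype(float))
        pred = rf.predict(ds.X[ho_mask])
        report.holdout[name] = {
            "mse": float(mean_squared_error(ds.y[ho_mask].astype(float), pred)),
            "r2": float(r2_score(ds.y[ho_mask].astype(float), pred)),
        }
        models[name] = rf
    report.n_train = bond_ds.n_rows + angle_ds.n_rows
    return ForceConstantModel(bond_regressor=models["bond"],
                              angle_regressor=models["angle"],
                              seed=seed), report


def predict_force_constants(model: ForceConstantModel, mol: Molecule,
                            internal: InternalCoordinates | None = None
                            ) -> tuple[dict, dict]:
    """Positive K_b per bond and K_theta per angle.

    Equilibrium values are taken from the structure itself, so only the
    stiffnesses are predicted here.
    """
    ic = internal if internal is not None else internal_coordinates(mol)
    bond_k = {}
    if ic.bonds:
        Xb = np.vstack([featurize_bond(mol, (i, j), model.manifest)
                        for i, j, _ in ic.bonds])
        for (i, j, _), k in zip(ic.bonds, model.bond_regressor.predict(Xb)):
            bond_k[(i, j)] = float(max(k, 1e-6))
    angle_k = {}
    if ic.angles:
        Xa = np.vstack([featurize_angle(mol, (i, j, k), model.manifest)
                        for i, j, k, _ in ic.angles])
        for (i, j, k, _), kv in zip(ic.angles,
                                    model.angle_regressor.predict(Xa)):
            angle_k[(i, j, k)] = float(max(kv, 1e-6))
    return bond_k, angle_k


# --------------------------------------------------------------------------
# Bundle persistence
# --------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """The five trained heads plus manifest and training metadata."""

    charge: ChargeModel
    atomtype: ClassifierModel
    phase: ClassifierModel
    periodicity: ClassifierModel
    force_constants: ForceConstantModel
    manifest: DescriptorManifest = DEFAULT_MANIFEST
    seed: int = 0
    reports: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str) -> "ModelBundle":
        return joblib.load(path)


def train_bundle(bundle_data, seed: int, cv_folds: int = 0) -> ModelBundle:
    """Train all five heads from a :class:`~ffforge.synthdata.TrainingBundle`."""
    charge, rep_c = train_charge_model(bundle_data.charges, seed,
                                       cv_folds=cv_folds)
    atomtype, rep_a = train_classifier("atomtype", bundle_data.atom_types,
                                       seed, cv_folds=cv_folds)
    phase, rep_p = train_classifier("phase", bundle_data.phase, seed,
                                    cv_folds=cv_folds)
    periodicity, rep_n = train_classifier("periodicity",
                                          bundle_data.periodicity, seed,
                                          cv_folds=cv_folds)
    fc, rep_f = train_force_constants(bundle_data.bond_k,
                                      bundle_data.angle_k, seed)
    return ModelBundle(charge=charge, atomtype=atomtype, phase=phase,
                       periodicity=periodicity, force_constants=fc,
                       seed=seed,
                       reports={"charges": rep_c, "atomtype": rep_a,
                                "phase": rep_p, "periodicity": rep_n,
                                "force_constants": rep_f})
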