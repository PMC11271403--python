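"""Self-supervised channel scrambling and patient embeddings.

The pretext task: synthesize an auxiliary dataset in which the heart-rate
and step-count channels of each window are dissociated across patients
(heart rate from patient A, steps from patient B), and train the CNN to
discriminate original from scrambled windows.  Because only original
windows carry genuine cross-channel temporal coupling, solving the task
forces the network to learn that coupling.  After training, the dropout
and sigmoid head are removed and the post-pooling 32-vector of each
first-week window, averaged per patient, is the patient embedding.

Patient-level 5-fold cross-validation: each fold holds out ~20% of
patients for early-stopping validation and scrambling draws donors from
the fold's training patients only.  Embedding defaults to a single
reference model (best held-out loss) so all patients share one
coordinate system; see :func:`embed_cohort` for the rationale and the
``out_of_fold`` audit mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cnn import CNNSpec, ConvNet1D
from .cohort import MINUTES_PER_WEEK
from .preprocessing import WindowTensor

logger = logging.getLogger(__name__)

HR, STEPS, MASK = 0, 1, 2


@dataclass
class ScrambledSample:
    values: np.ndarray            # (window, 3)
    label: int                    # 1 original, 0 scrambled
    hr_donor: str
    steps_donor: str


@dataclass
class ScrambledDataset:
    samples: list[ScrambledSample]

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.stack([s.values for s in self.samples])
        y = np.array([s.label for s in self.samples], dtype=float)
        return X, y


@dataclass
class TrainState:
    """Per-fold training record."""

    fold_index: int
    train_patients: list[str]
    heldout_patients: list[str]
    epochs_run: int
    train_loss: list[float]
    heldout_loss: list[float]
    heldout_accuracy: list[float]
    seed: int

    @property
    def best_heldout_accuracy(self) -> float:
        return max(self.heldout_accuracy)


@dataclass
class PatientEmbedding:
    patient_id: str
    vector: np.ndarray
    n_windows_used: int
    source_period: str = "first_week"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding contains non-finite values")


def _bucket(window: WindowTensor, bucket_hours: int = 4) -> int:
    t = window.window_start.astype("datetime64[s]")
    sec_of_day = int((t - t.astype("datetime64[D]")) / np.timedelta64(1, "s"))
    return (sec_of_day // 3600) // bucket_hours


def build_scrambled_dataset(windows: dict[str, list[WindowTensor]],
                            seed: int = 0,
                            match_time_of_day: bool = True) -> ScrambledDataset:
    """One scrambled negative per original window.

    For each original window (heart rate and steps from the same patient),
    a scrambled counterpart keeps the heart-rate channel and takes the
    step channel from a uniformly chosen window of a different patient —
    by default from the same 4-hour time-of-day bucket, so circadian phase
    alone cannot solve the task.  The scrambled mask is the elementwise
    union of the two donors' masks, keeping it truthful for both channels.
    Only windows flagged available are used.  Deterministic under seed.
    """
    avail = {pid: [w for w in ws if w.available] for pid, ws in windows.items()}
    avail = {pid: ws for pid, ws in avail.items() if ws}
    if len(avail) < 2:
        raise ValueError("cross-patient scrambling needs >= 2 patients "
                         "with available windows")
    rng = np.random.default_rng(seed)
    pids = sorted(avail)
    by_bucket: dict[int, list[tuple[str, WindowTensor]]] = {}
    for pid in pids:
        for w in avail[pid]:
            by_bucket.setdefault(_bucket(w) if match_time_of_day else 0,
                                 []).append((pid, w))

    samples: list[ScrambledSample] = []
    for pid in pids:
        for w in avail[pid]:
            samples.append(ScrambledSample(w.values.copy(), 1, pid, pid))
            pool = [(q, v) for q, v in by_bucket[_bucket(w) if match_time_of_day else 0]
                    if q != pid]
            if not pool:   # no other patient in this bucket: any other patient
                pool = [(q, v) for q in pids if q != pid for v in avail[q]]
            donor_pid, donor = pool[int(rng.integers(len(pool)))]
            vals = w.values.copy()
            vals[:, STEPS] = donor.values[:, STEPS]
            vals[:, MASK] = np.maximum(w.values[:, MASK], donor.values[:, MASK])
            # re-apply the neutral fill under the union mask
            vals[vals[:, MASK] == 1, HR] = 0.0
            vals[vals[:, MASK] == 1, STEPS] = 0.0
            samples.append(ScrambledSample(vals, 0, pid, donor_pid))
    return ScrambledDataset(samples)


def _first_week_split(windows: dict[str, list[WindowTensor]]
                      ) -> tuple[dict, dict]:
    """Split each patient's windows into first-week and later windows."""
    first, later = {}, {}
    for pid, ws in windows.items():
        if not ws:
            continue
        t0 = min(w.window_start for w in ws)
        cutoff = t0 + np.timedelta64(MINUTES_PER_WEEK * 60, "s")
        first[pid] = [w for w in ws if w.window_start < cutoff]
        later[pid] = [w for w in ws if w.window_start >= cutoff]
    return first, later


def patient_folds(patients: list[str], n_folds: int = 5,
                  seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """Partition patients into folds; each fold holds out ~1/n_folds."""
    if len(patients) < n_folds:
        raise ValueError("fewer patients than folds")
    rng = np.random.default_rng(seed)
    order = list(np.array(sorted(patients))[rng.permutation(len(patients))])
    held = [order[k::n_folds] for k in range(n_folds)]
    return [(sorted(set(order) - set(h)), sorted(h)) for h in held]


def train_discriminator(windows: dict[str, list[WindowTensor]],
                        spec: CNNSpec | None = None,
                        folds: int = 5,
                        epochs: int = 200,
                        patience: int = 10,
                        batch_size: int = 64,
                        seed: int = 0,
                        match_time_of_day: bool = True,
                        ) -> tuple[list[TrainState], list[ConvNet1D]]:
    """Train one discriminator per patient fold with early stopping.

    First-week windows are excluded from training everywhere (they are the
    evaluation material); scrambling donors come from each fold's training
    patients only, so held-out patients leak into neither channel of any
    training sample.  Early stopping monitors held-out BCE with the given
    patience; the best-epoch weights are restored.
    """
    spec = spec or CNNSpec()
    _, later = _first_week_split(windows)
    usable = sorted(pid for pid, ws in later.items()
                    if any(w.available for w in ws))
    fold_defs = patient_folds(usable, n_folds=folds, seed=seed)

    states, models = [], []
    window_len = next(w for ws in windows.values() for w in ws).values.shape[0]
    for k, (train_pids, held_pids) in enumerate(fold_defs):
        fold_seed = seed * 1000 + k
        ds_train = build_scrambled_dataset(
            {p: later[p] for p in train_pids}, seed=fold_seed,
            match_time_of_day=match_time_of_day)
        ds_held = build_scrambled_dataset(
            {p: later[p] for p in held_pids}, seed=fold_seed + 1,
            match_time_of_day=match_time_of_day)
        Xtr, ytr = ds_train.arrays()
        Xhe, yhe = ds_held.arrays()

        net = ConvNet1D(spec, input_len=window_len, seed=fold_seed)
        rng = np.random.default_rng(fold_seed + 7)
        best_loss, best_state, best_epoch = np.inf, net.state_dict(), 0
        tr_curve, he_curve, acc_curve = [], [], []
        for epoch in range(epochs):
            order = rng.permutation(len(ytr))
            losses = []
            for lo in range(0, len(order), batch_size):
                idx = order[lo:lo + batch_size]
                losses.append(net.train_batch(Xtr[idx], ytr[idx], rng))
            he_loss, he_acc = net.evaluate(Xhe, yhe)
            tr_curve.append(float(np.mean(losses)))
            he_curve.append(he_loss)
            acc_curve.append(he_acc)
            if he_loss < best_loss - 1e-6:
                best_loss, best_state, best_epoch = he_loss, net.state_dict(), epoch
            if epoch - best_epoch >= patience:
                break
        net.load_state_dict(best_state)
        states.append(TrainState(
            fold_index=k + 1, train_patients=list(train_pids),
            heldout_patients=list(held_pids), epochs_run=len(tr_curve),
            train_loss=tr_curve, heldout_loss=he_curve,
            heldout_accuracy=acc_curve, seed=fold_seed))
        models.append(net)
        logger.info("fold %d: %d epochs, best held-out loss %.4f acc %.3f",
                    k + 1, len(tr_curve), best_loss, acc_curve[best_epoch])
    return states, models


def embed_patient_first_week(model: ConvNet1D,
                             first_week_windows: list[WindowTensor]
                             ) -> PatientEmbedding:
    """Mean post-pooling embedding over a patient's available first-week windows."""
    avail = [w for w in first_week_windows if w.available]
    if not avail:
        raise ValueError("no available first-week windows for this patient")
    X = np.stack([w.values for w in avail])
    vecs = model.embed(X)
    return PatientEmbedding(patient_id=avail[0].patient_id,
                            vector=vecs.mean(axis=0),
                            n_windows_used=len(avail))


def embed_cohort(windows: dict[str, list[WindowTensor]],
                 states: list[TrainState],
                 models: list[ConvNet1D],
                 mode: str = "reference") -> dict[str, PatientEmbedding]:
    """First-week embeddings for every embeddable patient.

    ``mode="reference"`` (default) embeds the whole cohort with the single
    fold model whose held-out loss was best, so all embeddings share one
    coordinate system — a requirement for the downstream classifier.
    This is leakage-free for the embedded material: first-week windows
    are excluded from every fold's training data, and the pretext task
    never sees outcome labels.

    ``mode="out_of_fold"`` embeds each patient with the fold model that
    held them out entirely; embeddings then come from five different
    networks whose 32 coordinates are not mutually aligned, which a
    cross-patient classifier cannot exploit — retained for leakage
    audits, not for prediction.

    Patients without available first-week windows are excluded with a
    logged reason, mirroring the eligibility rule of the prediction task.
    """
    first, _ = _first_week_split(windows)
    out: dict[str, PatientEmbedding] = {}
    if mode == "reference":
        best = int(np.argmin([min(s.heldout_loss) for s in states]))
        model = models[best]
        for pid in sorted(first):
            try:
                out[pid] = embed_patient_first_week(model, first[pid])
            except ValueError as exc:
                logger.info("patient %s excluded from embedding: %s", pid, exc)
        return out
    if mode != "out_of_fold":
        raise ValueError(f"unknown embedding mode {mode!r}")
    for state, model in zip(states, models):
        for pid in state.heldout_patients:
            try:
                out[pid] = embed_patient_first_week(model, first.get(pid, []))
            except ValueError as exc:
                logger.info("patient %s excluded from embedding: %s", pid, exc)
    return out
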