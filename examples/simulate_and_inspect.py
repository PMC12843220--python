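"""Simulate a semi-supervised two-stage study and inspect its structure.

Generates the continuous two-stage observational design: a small labelled
cohort with outcomes Y2, Y3 plus a large unlabelled cohort where only
covariates, treatments and integer-valued outcome surrogates are recorded.
"""

import tempfile
from pathlib import Path

import numpy as np

from ssdtr import SimConfig, simulate, write_csv

cfg = SimConfig(setting="continuous2", n_labeled=135, N_unlabeled=1272, seed=1)
traj = simulate(cfg)

print(f"subjects: {traj.n_subjects} ({traj.n_labeled} labelled)")
lab = traj.labeled
print(f"Y2 observed on labelled rows: {np.isfinite(traj.Y[2][lab]).all()}")
print(f"Y2 masked on unlabelled rows: {np.isnan(traj.Y[2][~lab]).all()}")
print(f"mean Y2 (labelled): {np.nanmean(traj.Y[2]):.3f}")
corr = np.corrcoef(traj.W[2][lab, 0], traj.Y[3][lab])[0, 1]
print(f"corr(surrogate W2, outcome Y3) on labelled rows: {corr:.3f}")
path = Path(tempfile.gettempdir()) / "ssdtr_example_data.csv"
write_csv(traj, path)
print(f"wide CSV written to {path} (empty cells = masked outcomes)")

# The correlation near 0.9 is the engine of the semi-supervised gain: the
# surrogate carries most of the outcome signal onto the unlabelled subjects.
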