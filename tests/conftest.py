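import numpy as np
import pytest

from microrep import Exam, build_grid_10_2


@pytest.fixture(scope="session")
def grid():
    return build_grid_10_2()


@pytest.fixture
def make_exam(grid):
    """Factory: build an Exam from a scalar or per-locus array of thresholds."""

    def _make(values, patient_id="P000", eye="right", visit=1, test_index=2,
              fixation_loss_pct=0.0):
        vals = np.broadcast_to(np.asarray(values, float), (grid.n_loci,))
        return Exam(patient_id=patient_id, eye=eye, visit=visit,
                    test_index=test_index,
                    thresholds_db=dict(zip(grid.locus_ids, vals.astype(float))),
                    fixation_loss_pct=fixation_loss_pct)

    return _make
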