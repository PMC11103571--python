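import numpy as np
import pandas as pd
import pytest

from scpquant.io_tables import AnnotationSet, ChannelAnnotation, PSMRecord
from scpquant.matrix import QuantMatrix
from scpquant.pipeline import PipelineConfig, run_pipeline
from scpquant.synthetic import SynthConfig, generate_dataset


def make_psm(
    protein="P1",
    batch="b1",
    reporters=None,
    precursor=1000.0,
    fill_time=20.0,
    psm_id="psm0",
    **flags,
):
    return PSMRecord(
        psm_id=psm_id,
        protein_id=protein,
        batch_id=batch,
        reporter_intensity=np.asarray(reporters, dtype=float),
        precursor_intensity=precursor,
        fill_time=fill_time,
        **flags,
    )


def make_matrix(values, scale="log2", proteins=None, samples=None, meta=None):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=proteins, columns=samples)
    return QuantMatrix(df, scale=scale, sample_meta=meta)


@pytest.fixture
def small_annotation():
    """One 18-channel batch: carrier, reference, control, 15 single cells."""
    anns = [
        ChannelAnnotation("b1", 0, "carrier"),
        ChannelAnnotation("b1", 1, "reference"),
        ChannelAnnotation("b1", 2, "control"),
    ]
    for c in range(3, 18):
        anns.append(ChannelAnnotation("b1", c, "single_cell", "typeA" if c % 2 else "typeB"))
    return AnnotationSet(anns)


# --- session-scoped synthetic experiment reused by pipeline/acceptance tests ---

RECOVERY_SEED = 11


@pytest.fixture(scope="session")
def recovery_config():
    """Default-scale design with planted |log2 FC| = 1 effects."""
    return SynthConfig(dep_log2fc_choices=(1.0,))


@pytest.fixture(scope="session")
def recovery_dataset(recovery_config):
    return generate_dataset(recovery_config, seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def recovery_dir(recovery_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("synth")
    recovery_dataset.write(out)
    return out


@pytest.fixture(scope="session")
def recovery_run(recovery_dir, tmp_path_factory):
    config = PipelineConfig(
        psm_paths=sorted(str(p) for p in recovery_dir.glob("*.evidence.tsv")),
        annotation_path=str(recovery_dir / "annotation.tsv"),
        protein_groups_path=str(recovery_dir / "proteinGroups.tsv"),
        out_dir=str(tmp_path_factory.mktemp("run")),
        seed=RECOVERY_SEED,
    )
    return run_pipeline(config)
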