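import numpy as np
import pytest

from merip_enrich.models import ReadLibrary, TranscriptModel, reads_as_array
from merip_enrich.peaks import call_peaks_by_condition
from merip_enrich.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def coding_model():
    """Length-600 transcript with UTR5 [0,100), CDS [100,400), UTR3 [400,600)."""
    return TranscriptModel(
        gene_id="geneA", transcript_id="txA", length=600, cds_start=100, cds_end=400
    )


@pytest.fixture
def noncoding_model():
    return TranscriptModel(gene_id="geneN", transcript_id="txN", length=400)


def make_library(reads_by_tid, sample_id="s1", condition="parental", replicate=1,
                 assay="input", total_mapped=0):
    reads = {tid: reads_as_array(ivals) for tid, ivals in reads_by_tid.items()}
    return ReadLibrary(
        sample_id=sample_id,
        condition=condition,
        replicate=replicate,
        assay=assay,
        reads=reads,
        total_mapped=total_mapped,
    )


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: 100 genes, 5e5 reads/library, enrichment 8."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def study_peaks(study):
    return call_peaks_by_condition(study.libraries, study.models)
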