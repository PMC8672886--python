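import pytest

from erv_atlas import detect, pipeline, simulate


@pytest.fixture(scope="session")
def small_planted():
    """1 Mb background with five planted elements of mixed structure."""
    genome = {"chr1": simulate.generate_background(1_000_000, 0.384, 11)}
    specs = pipeline.default_benchmark_specs(5, 2.0, seed=5)
    return simulate.plant_elements(genome, specs, min_gap=20_000, seed=7)


@pytest.fixture(scope="session")
def small_detected(small_planted):
    genome, truth = small_planted
    elements = detect.detect_elements(genome["chr1"], chrom="chr1")
    return genome, truth, elements
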