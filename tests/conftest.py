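import random
from types import SimpleNamespace

import pytest

from srannot import (
    accumulate,
    annotate_read,
    build_feature_set,
    build_index,
    parse_config,
    read_alignment_sets,
    read_gtf,
)
from srannot.simulate import worked_example


def run_pipeline(
    gtf_text: str,
    config_text: str,
    sam_text: str,
    tmp_path,
    strategy: str = "default",
    seed: int = 0,
    overlap_threshold=None,
    vicinity_size: int | None = None,
    config=None,
):
    """Run the full annotation pipeline on in-memory inputs.

    Returns a namespace with the per-read annotations, the three result
    tables and the feature set, for assertion convenience.
    """
    gtf = tmp_path / "annotation.gtf"
    gtf.write_text(gtf_text)
    sam = tmp_path / "reads.sam"
    sam.write_text(sam_text)
    cfg = config if config is not None else parse_config(config_text)
    if overlap_threshold is not None:
        cfg.overlap_threshold = overlap_threshold
    if vicinity_size is not None:
        cfg.vicinity_size = vicinity_size

    import pysam

    with pysam.AlignmentFile(str(sam), check_sq=False) as af:
        chrom_lengths = dict(zip(af.references or (), af.lengths or ()))

    features = build_feature_set(read_gtf(gtf), cfg, chrom_lengths=chrom_lengths)
    index = build_index(features)
    rng = random.Random(seed)
    annotations = {}

    def results():
        for read_set in read_alignment_sets(sam):
            resolved, contribs = annotate_read(
                read_set, index, cfg, strategy=strategy, rng=rng
            )
            annotations[read_set.read_id] = resolved
            yield read_set.read_id, contribs

    counts, feature_counts, stats = accumulate(results())
    return SimpleNamespace(
        annotations=annotations,
        counts=counts,
        feature_counts=feature_counts,
        stats=stats,
        features=features,
        config=cfg,
    )


@pytest.fixture(scope="session")
def scenario():
    return worked_example()


@pytest.fixture
def worked_example_result(scenario, tmp_path):
    return run_pipeline(scenario.gtf_text, scenario.config_text, scenario.sam_text, tmp_path)
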