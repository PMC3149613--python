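import dataclasses

import pytest

from strainscan import ScanConfig, run_scan
from strainscan.config import PrefilterConfig
from strainscan.report import render_report
from strainscan.synth import flagship_spec, make_pair, silent_spec, smoke_spec

FIXTURE_SEED = 101


@pytest.fixture(scope="session")
def default_config():
    return ScanConfig()


@pytest.fixture(scope="session")
def smoke_pair():
    return make_pair(smoke_spec(FIXTURE_SEED))


@pytest.fixture(scope="session")
def smoke_result(smoke_pair, default_config):
    ancestor, mutant, _ = smoke_pair
    return run_scan(ancestor, mutant, [a.gene_name for a in ancestor.annotations], default_config)


@pytest.fixture(scope="session")
def silent_pair():
    return make_pair(silent_spec(FIXTURE_SEED))


@pytest.fixture(scope="session")
def flagship_pair():
    return make_pair(flagship_spec(FIXTURE_SEED))


@pytest.fixture(scope="session")
def flagship_result(flagship_pair, default_config):
    ancestor, mutant, _ = flagship_pair
    return run_scan(ancestor, mutant, [a.gene_name for a in ancestor.annotations], default_config)


@pytest.fixture(scope="session")
def flagship_report(flagship_result):
    return render_report(flagship_result.rows)


@pytest.fixture(scope="session")
def flagship_report_noprefilter(flagship_pair, default_config):
    ancestor, mutant, _ = flagship_pair
    config = dataclasses.replace(default_config, prefilter=PrefilterConfig(enabled=False))
    result = run_scan(ancestor, mutant, [a.gene_name for a in ancestor.annotations], config)
    return render_report(result.rows)
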