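import pytest

from ctdflow import fixtures as fx


@pytest.fixture()
def pdbcutter():
    return fx.pdbcutter_descriptor()


@pytest.fixture()
def lfq_source():
    return fx.lfq_source_workflow()


@pytest.fixture()
def echo_stub(tmp_path):
    return fx.make_echo_stub(tmp_path)
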