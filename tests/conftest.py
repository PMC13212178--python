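import pytest

from qualcbma import example_checklist_text, load_checklist


@pytest.fixture(scope="session")
def example_doc():
    """The packaged worked-example checklist document."""
    return load_checklist(example_checklist_text())
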