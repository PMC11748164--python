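"""Shared exception types."""


class SeamtubeError(RuntimeError):
    """Base class for package errors."""


class EngineError(SeamtubeError):
    """An external electronic-structure engine failed or returned an
    invalid response; the message carries the captured engine output."""
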