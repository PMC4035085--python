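"""Exception hierarchy shared across the pipeline."""


class Pr77KitError(Exception):
    """Base class for all pr77kit errors."""


class InputError(Pr77KitError, ValueError):
    """Malformed or out-of-contract user input (CLI exit code 1)."""


class ParameterError(Pr77KitError, ValueError):
    """A configuration knob outside its permitted range."""


class UnsatisfiableDescriptorError(Pr77KitError, ValueError):
    """The structural descriptor admits no sequence; names the binding constraint."""
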