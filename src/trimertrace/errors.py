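class ValidationError(ValueError):
    """Invalid user input (bad parameter, malformed spec).

    ``field`` names the offending parameter when known, so callers and the
    CLI can report it without parsing the message.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field
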