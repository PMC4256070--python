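"""Exception types shared across channelkit."""


class ChannelkitError(Exception):
    """Base class for all channelkit errors."""


class StructureError(ChannelkitError):
    """Invalid or unusable coarse structure input."""


class SelectorError(ChannelkitError):
    """A residue selector did not resolve to a unique residue."""


class NetworkError(ChannelkitError):
    """Elastic-network construction or decomposition failure."""


class TableError(ChannelkitError):
    """Malformed tabular input (couplings, tracks, scales)."""


class AnalysisError(ChannelkitError):
    """An analysis operation received inconsistent inputs."""
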