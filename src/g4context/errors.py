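class G4DataError(ValueError):
    """Malformed or inconsistent input data (FASTA, candidate table, profiles)."""
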