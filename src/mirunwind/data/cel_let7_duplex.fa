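>cel-let-7 mature 5p and 3p arms (miRBase v22.1), cofold dialect
UGAGGUAGUAGGUUGUAUAGUU&CUAUGCAAUUUUCUACCUUACC
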