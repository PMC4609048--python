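{
 "adverse_effects.tsv": "0836390548de04d57df8fe981535489ffda15ef62575e37a89cacc4c784df4bc",
 "effectiveness_arms.tsv": "3290ce18d856851208f48cd714b76d04838efd330cb93514fe879a27ffa60ebc",
 "nonserious_arms.tsv": "2167707b614a46d57bab19321a9a0e397f47507e56a9c64a242e79eb4b091afb",
 "risk_limits.tsv": "46eda22561c415822bf238727c95787119421c357b8d96d4e93935e9a682315b"
}
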