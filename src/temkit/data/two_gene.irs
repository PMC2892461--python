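# Two-component activator/repressor pair: x activates y, y represses x.
var x
var y
interact x + y
interact y - x
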