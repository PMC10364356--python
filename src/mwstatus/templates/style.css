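body { font-family: sans-serif; margin: 2em auto; max-width: 60em; color: #222; }
h1, h2 { color: #1a3c5e; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #bbb; padding: 0.3em 0.8em; text-align: left; }
th { background: #eef3f8; }
.badge { padding: 0.15em 0.5em; border-radius: 0.4em; font-size: 0.9em; white-space: nowrap; }
.st-passing { background: #d4edda; color: #155724; }
.st-parsing-error { background: #f8d7da; color: #721c24; }
.st-validation-error { background: #fff3cd; color: #856404; }
.st-missing { background: #e2e3e5; color: #383d41; }
.st-consistent { background: #d4edda; color: #155724; }
.st-inconsistent { background: #f8d7da; color: #721c24; }
.st-not-checked { background: #e2e3e5; color: #383d41; }
footer { margin-top: 2em; font-size: 0.8em; color: #666; }
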