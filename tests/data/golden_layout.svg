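<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" width="800.000" height="29.773" viewBox="0 0 800.000 29.773">
<g class="edges" stroke="#000000" stroke-width="0.500">
<line x1="98.291" y1="13.223" x2="98.291" y2="13.223"/>
<line x1="164.497" y1="10.589" x2="164.497" y2="10.589"/>
<line x1="238.118" y1="10.000" x2="238.118" y2="10.000"/>
<line x1="326.430" y1="13.068" x2="326.430" y2="13.068"/>
<line x1="392.697" y1="14.404" x2="392.697" y2="14.404"/>
<line x1="466.290" y1="17.406" x2="466.290" y2="17.406"/>
<line x1="547.392" y1="19.773" x2="547.393" y2="19.773"/>
<line x1="591.266" y1="12.864" x2="591.265" y2="12.864"/>
<line x1="620.734" y1="13.986" x2="620.733" y2="13.986"/>
<line x1="664.962" y1="13.450" x2="664.962" y2="13.450"/>
<line x1="709.078" y1="16.241" x2="709.078" y2="16.241"/>
</g>
<g class="nodes" stroke-width="2.000" stroke-linecap="round">
<line x1="10.000" y1="16.534" x2="98.291" y2="13.223" stroke="#3465a4"/>
<line x1="98.291" y1="13.223" x2="164.497" y2="10.589" stroke="#3465a4"/>
<line x1="164.497" y1="10.589" x2="238.118" y2="10.000" stroke="#3465a4"/>
<line x1="238.118" y1="10.000" x2="326.430" y2="13.068" stroke="#3465a4"/>
<line x1="326.430" y1="13.068" x2="392.697" y2="14.404" stroke="#3465a4"/>
<line x1="392.697" y1="14.404" x2="466.290" y2="17.406" stroke="#3465a4"/>
<line x1="466.290" y1="17.406" x2="547.392" y2="19.773" stroke="#3465a4"/>
<line x1="547.393" y1="19.773" x2="591.266" y2="12.864" stroke="#3465a4"/>
<line x1="591.265" y1="12.864" x2="620.734" y2="13.986" stroke="#3465a4"/>
<line x1="620.733" y1="13.986" x2="664.962" y2="13.450" stroke="#3465a4"/>
<line x1="664.962" y1="13.450" x2="709.078" y2="16.241" stroke="#3465a4"/>
<line x1="709.078" y1="16.241" x2="790.000" y2="13.162" stroke="#3465a4"/>
</g>
</svg>
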