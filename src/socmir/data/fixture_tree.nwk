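(isca,(acpi,(tcas,(bmor,((dmel,aaeg),(aros,((mdem,(nvit,(nlon,ngir))),(pdom,((hsal,(cflo,(sinv,(pbar,acep)))),(mrot,(lalb,((bimp,bter),(amel,(ador,aflo))))))))))))));
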